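"""Interface residue mapping, burial classification, and ligand-proximity listing.

These are the tools used to ask where a mutated residue sits in an oligomer:
at a chain-chain interface (heavy atoms of the two chains within a cutoff),
buried in the core or exposed on the surface (a neighbour-count proxy for
solvent accessibility), or near an arbitrary set of site points such as a
docked cofactor. Hydrogens are excluded everywhere; models are typically
hydrogen-free. Distances are computed by exact all-pairs evaluation — the
structures involved are small enough that no spatial index is needed.

The burial thresholds (buried >= 28 and exposed <= 18 C-alpha neighbours
within 10 A) are package conventions, flagged in report headers, since no
standard cutoff exists for qualitative buried/surface calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import EmptyInputError, ResidueNotFoundError
from .structio import AtomRecord, Structure


class BurialClass(str, Enum):
    BURIED = "buried"
    INTERMEDIATE = "intermediate"
    EXPOSED = "exposed"


@dataclass
class InterfaceEntry:
    chain_id: str
    residue_number: int
    residue_name: str
    min_distance: float  # A, closest heavy atom on the partner chain
    contact_count: int  # heavy-atom pairs within the cutoff


@dataclass
class InterfaceReport:
    chain_pair: tuple[str, str]
    entries: list[InterfaceEntry]
    cutoff_used: float

    def residue_set(self) -> set[tuple[str, int]]:
        return {(e.chain_id, e.residue_number) for e in self.entries}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# interface report, chains {self.chain_pair[0]}-{self.chain_pair[1]}, "
                f"heavy-atom cutoff {self.cutoff_used:g} A (package convention)\n"
            )
            fh.write("chain\tresnum\tresname\tmin_dist_A\tcontacts\n")
            for e in self.entries:
                fh.write(
                    f"{e.chain_id}\t{e.residue_number}\t{e.residue_name}\t"
                    f"{e.min_distance:.3f}\t{e.contact_count}\n"
                )


def _heavy_atoms(structure: Structure) -> list[AtomRecord]:
    return [a for a in structure.atoms if a.is_heavy()]


def interface_residues(
    structure: Structure, chain_a: str, chain_b: str, cutoff: float = 5.0
) -> InterfaceReport:
    """Residues of either chain with >= 1 heavy atom within ``cutoff`` of the other chain."""
    atoms_a = _heavy_atoms(structure.chain(chain_a))
    atoms_b = _heavy_atoms(structure.chain(chain_b))
    entries: list[InterfaceEntry] = []
    if atoms_a and atoms_b:
        ca = np.array([a.coordinates for a in atoms_a])
        cb = np.array([a.coordinates for a in atoms_b])
        dmat = cdist(ca, cb)
        for atoms, dists in ((atoms_a, dmat), (atoms_b, dmat.T)):
            per_residue: dict[tuple, dict] = {}
            for atom, row in zip(atoms, dists):
                rec = per_residue.setdefault(
                    atom.residue_key,
                    {"name": atom.residue_name, "min": np.inf, "contacts": 0},
                )
                rec["min"] = min(rec["min"], float(row.min()))
                rec["contacts"] += int(np.sum(row <= cutoff))
            for (cid, resnum, _icode), rec in per_residue.items():
                if rec["min"] <= cutoff:
                    entries.append(
                        InterfaceEntry(cid, resnum, rec["name"], rec["min"], rec["contacts"])
                    )
    entries.sort(key=lambda e: (e.chain_id, e.residue_number))
    return InterfaceReport((chain_a, chain_b), entries, cutoff)


def burial_class(
    structure: Structure,
    chain: str,
    residue_number: int,
    radius: float = 10.0,
    thresholds: tuple[int, int] = (28, 18),
) -> tuple[BurialClass, int]:
    """Classify a residue as buried/intermediate/exposed by C-alpha neighbour count.

    Counts C-alpha atoms of *all* chains within ``radius`` of the residue's own
    C-alpha (the residue center of geometry when no C-alpha exists). The residue's
    own reference atom is not counted. ``thresholds`` is (buried >=, exposed <=).
    """
    buried_min, exposed_max = thresholds
    target_atoms = [
        a
        for a in structure.chain(chain).atoms
        if a.residue_number == residue_number
    ]
    if not target_atoms:
        raise ResidueNotFoundError(
            f"residue {residue_number} not found in chain {chain!r}"
        )
    ca = [a for a in target_atoms if a.atom_name.strip() == "CA"]
    center = (
        ca[0].coordinates
        if ca
        else np.mean([a.coordinates for a in target_atoms], axis=0)
    )

    count = 0
    for a in structure.atoms:
        if a.atom_name.strip() != "CA":
            continue
        if a.chain_id == chain and a.residue_number == residue_number:
            continue
        if np.linalg.norm(a.coordinates - center) <= radius:
            count += 1
    if count >= buried_min:
        cls = BurialClass.BURIED
    elif count <= exposed_max:
        cls = BurialClass.EXPOSED
    else:
        cls = BurialClass.INTERMEDIATE
    return cls, count


def residues_near_points(
    structure: Structure, points, cutoff: float = 4.5
) -> list[tuple[str, int, str]]:
    """Unique residues with any heavy atom within ``cutoff`` of any query point, sorted."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise EmptyInputError("residues_near_points requires at least one query point")
    heavy = _heavy_atoms(structure)
    if not heavy:
        return []
    coords = np.array([a.coordinates for a in heavy])
    near = cdist(coords, pts).min(axis=1) <= cutoff
    found = {
        (a.chain_id, a.residue_number, a.residue_name)
        for a, hit in zip(heavy, near)
        if hit
    }
    return sorted(found)
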
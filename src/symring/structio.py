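"""Read, write and subset protein structures in fixed-column PDB format.

The in-memory model is deliberately flat: a :class:`Structure` is an ordered
list of :class:`AtomRecord` objects plus free-form metadata. Chains and
residues are derived views, which keeps rigid-body operations (that only touch
coordinates) cheap and explicit.

Parsing is delegated to :mod:`gemmi`; only the first model is kept and, for
atoms with alternate locations, only the first-listed conformer. HETATM
records (e.g. a placed cofactor) are parsed into the same structure under
their own chain id so that proximity searches can see them. Writing uses a
fixed-column formatter so TER placement and 3-decimal coordinates follow the
classic PDB layout exactly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .exceptions import (
    ChainNotFoundError,
    CoordinateOverflowError,
    EmptyInputError,
    PDBFormatError,
)

#: chain labels usable in the single-character PDB chain-id column
CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass
class AtomRecord:
    """One atom: identity plus Cartesian coordinates in Angstrom."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray  # shape (3,), Angstrom
    element: str = ""
    insertion_code: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_number, insertion_code) — unique residue identifier."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    def is_heavy(self) -> bool:
        """True unless the atom is hydrogen/deuterium."""
        el = (self.element or "").strip().upper()
        if not el:
            stripped = self.atom_name.strip().lstrip("0123456789")
            el = stripped[:1].upper()
        return el not in ("H", "D")


class Structure:
    """An ordered collection of atoms with derived chain/residue views."""

    def __init__(self, atoms: Iterable[AtomRecord], metadata: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.metadata = metadata

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Structure {len(self.atoms)} atoms, chains {''.join(self.chains)!r}>"

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (a copy), Angstrom."""
        if not self.atoms:
            return np.empty((0, 3), dtype=float)
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with coordinates replaced (same atom identities)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        new_atoms = [replace(a, coordinates=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(new_atoms, metadata=self.metadata)

    def chain(self, chain_id: str) -> "Structure":
        """Substructure of one chain; raises if the chain is absent."""
        if chain_id not in self.chains:
            raise ChainNotFoundError(
                f"chain {chain_id!r} not found; available chains: {self.chains}"
            )
        return Structure([a for a in self.atoms if a.chain_id == chain_id], self.metadata)

    def relabel_chains(self, mapping: dict[str, str]) -> "Structure":
        new_atoms = [
            replace(a, chain_id=mapping.get(a.chain_id, a.chain_id)) for a in self.atoms
        ]
        return Structure(new_atoms, metadata=self.metadata)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Iterate residues in atom order as (residue_key, atoms)."""
        current_key: tuple[str, int, str] | None = None
        bucket: list[AtomRecord] = []
        for a in self.atoms:
            if a.residue_key != current_key:
                if bucket:
                    yield current_key, bucket  # type: ignore[misc]
                current_key, bucket = a.residue_key, []
            bucket.append(a)
        if bucket:
            yield current_key, bucket  # type: ignore[misc]

    @staticmethod
    def concat(parts: Sequence["Structure"], metadata: str = "") -> "Structure":
        """Concatenate structures, renumbering serials sequentially."""
        atoms: list[AtomRecord] = []
        for part in parts:
            atoms.extend(part.atoms)
        atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
        return Structure(atoms, metadata=metadata)


def read_pdb(path: str | os.PathLike) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Both ATOM and HETATM records are kept. Only the first MODEL is read and
    only the first-listed alternate conformer of each atom is retained.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(path)
    except Exception as exc:  # gemmi raises RuntimeError on malformed input
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    st.remove_alternative_conformations()  # keeps the first-listed conformer

    atoms: list[AtomRecord] = []
    if len(st) > 0:
        model = st[0]  # first model only
        serial = 0
        for chain in model:
            for res in chain:
                hetero = res.het_flag == "H"
                for atom in res:
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            atom_name=atom.name,
                            residue_name=res.name,
                            chain_id=chain.name,
                            residue_number=res.seqid.num,
                            coordinates=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                            ),
                            element=atom.element.name,
                            insertion_code=(res.seqid.icode or "").strip(),
                            hetero=hetero,
                        )
                    )
    if not atoms:
        with open(path, "r", errors="replace") as fh:
            first_line = fh.readline().rstrip("\n")
        raise PDBFormatError(
            f"no ATOM/HETATM records in {path} (first line: {first_line!r})"
        )
    return Structure(atoms, metadata=st.name or "")


def _format_atom_name(name: str) -> str:
    # Names shorter than 4 characters start in column 14 per the PDB convention.
    name = name.strip()
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write fixed-column PDB ATOM/HETATM records, one TER per chain.

    Coordinates are printed to 3 decimals; magnitudes >= 10000 A do not fit the
    8-column field and raise :class:`CoordinateOverflowError`.
    """
    if len(structure) == 0:
        raise EmptyInputError("cannot write an empty structure")
    chains = structure.chains
    if len(chains) > len(CHAIN_ALPHABET):
        raise ValueError(f">{len(CHAIN_ALPHABET)} chains unsupported in PDB chain-id column")
    coords = structure.coords
    if np.any(np.abs(coords) >= 10000.0):
        worst = float(np.max(np.abs(coords)))
        raise CoordinateOverflowError(
            f"coordinate magnitude {worst:.1f} A does not fit PDB fixed columns (>= 10000 A)"
        )

    lines: list[str] = []
    if structure.metadata:
        lines.append(f"TITLE     {structure.metadata[:70]}")
    serial = 0
    for cid in chains:
        last: AtomRecord | None = None
        for atom in structure.atoms:
            if atom.chain_id != cid:
                continue
            serial += 1
            record = "HETATM" if atom.hetero else "ATOM  "
            element = (atom.element or atom.atom_name.strip()[:1]).strip()[:2].rjust(2)
            x, y, z = atom.coordinates
            lines.append(
                f"{record}{serial % 100000:>5} {_format_atom_name(atom.atom_name)} "
                f"{atom.residue_name:>3} {cid[:1]}{atom.residue_number:>4}"
                f"{(atom.insertion_code or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element}"
            )
            last = atom
        assert last is not None
        serial += 1
        lines.append(
            f"TER   {serial % 100000:>5}      {last.residue_name:>3} "
            f"{cid[:1]}{last.residue_number:>4}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def select_atoms(
    structure: Structure,
    chain_ids: set[str] | Sequence[str] | None = None,
    atom_names: set[str] | Sequence[str] | None = None,
) -> Structure:
    """Subset by chain ids and/or atom names. An empty result warns, not errors."""
    chain_set = set(chain_ids) if chain_ids is not None else None
    name_set = {n.strip() for n in atom_names} if atom_names is not None else None
    kept = [
        a
        for a in structure.atoms
        if (chain_set is None or a.chain_id in chain_set)
        and (name_set is None or a.atom_name.strip() in name_set)
    ]
    if not kept:
        warnings.warn("select_atoms: selection matched no atoms", stacklevel=2)
    return Structure(kept, metadata=structure.metadata)
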
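"""Coarse-grained inter-chain scoring for rigid-body assemblies.

The score is a capped 12-6 Lennard-Jones potential summed over inter-chain
atom pairs within a cutoff, by default on C-alpha atoms only. It is a
deliberately simple, self-contained pair potential: the landscape analysis
only needs the qualitative structure of the energy surface — where rings
clash and where they pack favourably — which a clash-aware pair potential
captures. Pairs inside a chain are ignored, so the score measures only how
chains sit against each other. No minimisation is performed; scoring is a
deterministic function of the coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ChainCountError
from .structio import Structure, select_atoms


@dataclass
class EnergySettings:
    """Parameters of the capped Lennard-Jones inter-chain score.

    epsilon : well depth, kcal/mol
    sigma : zero-crossing distance, A (minimum at 2^(1/6) sigma)
    cutoff : pair-list cutoff, A; pairs at or beyond it contribute nothing
    per_pair_cap : maximum energy a single pair may contribute, kcal/mol
    atom_selection : "CA_only" (default) or "all_atoms"
    """

    epsilon: float = 0.2
    sigma: float = 5.0
    cutoff: float = 12.0
    per_pair_cap: float = 100.0
    atom_selection: str = "CA_only"

    def __post_init__(self) -> None:
        if min(self.epsilon, self.sigma, self.cutoff, self.per_pair_cap) <= 0:
            raise ValueError("all energy settings must be positive")
        if self.cutoff <= self.sigma:
            raise ValueError(f"cutoff ({self.cutoff}) must exceed sigma ({self.sigma})")
        if self.atom_selection not in ("CA_only", "all_atoms"):
            raise ValueError(f"unknown atom_selection {self.atom_selection!r}")

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "sigma": self.sigma,
            "cutoff": self.cutoff,
            "per_pair_cap": self.per_pair_cap,
            "atom_selection": self.atom_selection,
        }


DEFAULT_SETTINGS = EnergySettings()


def _scored_atoms(structure: Structure, settings: EnergySettings) -> Structure:
    if settings.atom_selection == "CA_only":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = select_atoms(structure, atom_names={"CA"})
        if len(sub) == 0:
            warnings.warn(
                "no CA atoms found; falling back to all atoms for scoring", stacklevel=3
            )
            return structure
        return sub
    return structure


def _inter_chain_pairs(
    structure: Structure, settings: EnergySettings, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Distances of all inter-chain atom pairs closer than ``radius`` (inclusive).

    Returns (distances, pair index array). Requires >= 2 chains.
    """
    sub = _scored_atoms(structure, settings)
    chains = sub.chains
    if len(chains) < 2:
        raise ChainCountError(
            f"inter-chain scoring requires >= 2 chains, structure has {len(chains)}"
        )
    coords = sub.coords
    chain_index = {c: i for i, c in enumerate(chains)}
    labels = np.array([chain_index[a.chain_id] for a in sub.atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0), pairs
    mask = labels[pairs[:, 0]] != labels[pairs[:, 1]]
    pairs = pairs[mask]
    dists = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return dists, pairs


def pair_energy(r: np.ndarray | float, settings: EnergySettings = DEFAULT_SETTINGS):
    """Capped 12-6 Lennard-Jones energy of a pair at distance r (vectorised)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = settings.sigma / r
        e = 4.0 * settings.epsilon * (inv**12 - inv**6)
    e = np.where(np.isfinite(e), e, settings.per_pair_cap)
    return np.minimum(e, settings.per_pair_cap)


def interchain_energy(
    structure: Structure, settings: EnergySettings = DEFAULT_SETTINGS
) -> float:
    """Sum of capped pair energies over inter-chain pairs with r < cutoff (kcal/mol)."""
    dists, _ = _inter_chain_pairs(structure, settings, settings.cutoff)
    if dists.size == 0:
        return 0.0
    dists = dists[dists < settings.cutoff]
    if dists.size == 0:
        return 0.0
    return float(np.sum(pair_energy(dists, settings)))


def clash_count(
    structure: Structure,
    threshold: float = 3.0,
    atom_selection: str = "CA_only",
) -> int:
    """Number of inter-chain atom pairs closer than ``threshold`` Angstrom."""
    settings = EnergySettings(atom_selection=atom_selection)
    dists, _ = _inter_chain_pairs(structure, settings, threshold)
    return int(np.sum(dists < threshold))
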
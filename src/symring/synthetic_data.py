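"""Synthetic inputs with known ground truth for every stage of the pipeline.

Structures are C-alpha-only toys: an ideal helix, a "helical bundle" shell
tracing a cylinder of globular-subunit girth, or a random cloud. The bundle
default radius (20 A) gives the toy monomer the ~40 A footprint of a
globular, ~380-residue subunit such as a methanol dehydrogenase monomer, so
that a 40-50 A neighbour-distance scan spans the physically interesting
touching-to-separated regime.

Kinetic and growth generators embed their ground truth in the returned
object's ``truth`` metadata. Every generator is a pure function of its
spec + seed (bit-reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import superpose
from .kinetics import ProgressCurve, RateDataset, michaelis_menten
from .structio import AtomRecord, Structure

_SHAPES = ("helix", "helical_bundle", "random_cloud")

#: C-alpha distance from an ideal alpha-helix axis
ALPHA_HELIX_RADIUS = 2.3
#: cylinder radius of the helical_bundle shell (globular-subunit footprint)
BUNDLE_RADIUS = 20.0
#: radius of the uniform ball used for random clouds
CLOUD_RADIUS = 10.0


@dataclass
class ToySpec:
    """Recipe for a deterministic C-alpha toy monomer."""

    n_residues: int
    shape: str = "helix"
    rise: float = 1.5  # A per residue along z
    twist: float = 100.0  # degrees per residue
    radius: float | None = None  # shape-dependent default when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError(f"n_residues must be >= 3, got {self.n_residues}")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")


def _ca_structure(coords: np.ndarray, chain_id: str = "A", metadata: str = "") -> Structure:
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name="CA",
            residue_name="ALA",
            chain_id=chain_id,
            residue_number=i + 1,
            coordinates=coords[i],
            element="C",
        )
        for i in range(coords.shape[0])
    ]
    return Structure(atoms, metadata=metadata)


def make_toy_monomer(spec: ToySpec) -> Structure:
    """One CA pseudo-atom per residue; residues 1..n in chain A."""
    n = spec.n_residues
    if spec.shape in ("helix", "helical_bundle"):
        radius = spec.radius
        if radius is None:
            radius = ALPHA_HELIX_RADIUS if spec.shape == "helix" else BUNDLE_RADIUS
        i = np.arange(n)
        theta = np.radians(spec.twist) * i
        coords = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), spec.rise * i]
        )
    else:  # random_cloud: uniform in a ball
        radius = CLOUD_RADIUS if spec.radius is None else spec.radius
        rng = np.random.default_rng(spec.seed)
        direction = rng.normal(size=(n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        r = radius * rng.random(n) ** (1.0 / 3.0)
        coords = direction * r[:, None]
    return _ca_structure(
        coords, metadata=f"toy monomer {spec.shape} n={n} seed={spec.seed}"
    )


def make_c2_dimer_template(
    monomer: Structure, separation: float, axis=(0.0, 0.0, 1.0)
) -> Structure:
    """Exact C2 dimer: chain B is chain A rotated 180 deg about ``axis``.

    The monomer is offset perpendicular to the axis so the two chain centers
    of geometry end up ``separation`` apart; the C2 axis passes through the
    dimer center. For the default z axis the 180-degree map is the exact sign
    flip diag(-1,-1,1), so the symmetry holds to the last bit.
    """
    if len(monomer.chains) != 1:
        raise ValueError("template construction expects a single-chain monomer")
    if separation < 0:
        raise ValueError(f"separation must be non-negative, got {separation}")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    # perpendicular offset direction (prefer +x)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(axis @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - (trial @ axis) * axis
    perp /= np.linalg.norm(perp)

    coords = monomer.coords
    cog = coords.mean(axis=0)
    a_coords = coords - cog + perp * (separation / 2.0)
    if np.allclose(axis, [0.0, 0.0, 1.0]):
        c2 = np.diag([-1.0, -1.0, 1.0])  # exact for the z axis
    else:
        outer = np.outer(axis, axis)
        c2 = 2.0 * outer - np.eye(3)
    b_coords = a_coords @ c2.T

    chain_a = monomer.with_coords(a_coords).relabel_chains(
        {monomer.chains[0]: "A"}
    )
    chain_b = monomer.with_coords(b_coords).relabel_chains(
        {monomer.chains[0]: "B"}
    )
    return Structure.concat(
        [chain_a, chain_b], metadata=f"C2 dimer template, separation {separation:g} A"
    )


def simulate_mm_rates(
    km: float,
    vmax: float,
    concentrations,
    noise_cv: float = 0.0,
    seed: int = 0,
    enzyme_conc: float | None = None,
) -> RateDataset:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise.

    v_i = Vmax*S_i/(Km+S_i) * (1 + eps_i), eps_i ~ N(0, noise_cv).
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    s = np.asarray(concentrations, dtype=float)
    if s.size == 0:
        raise ValueError("concentration list must be non-empty")
    rng = np.random.default_rng(seed)
    v = michaelis_menten(s, vmax, km)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=s.shape))
    return RateDataset(
        substrate_conc=s,
        initial_rate=v,
        enzyme_conc=enzyme_conc,
        truth={"Km": km, "Vmax": vmax, "noise_cv": noise_cv, "seed": seed},
    )


def simulate_decay(
    initial: float,
    half_life: float,
    duration: float,
    step: float,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ProgressCurve:
    """Exponential decay sampled on a uniform grid: value = initial * 2^(-t/half_life)."""
    if min(initial, half_life, duration, step) <= 0:
        raise ValueError("initial, half_life, duration and step must be positive")
    if step >= duration:
        raise ValueError(f"step ({step}) must be smaller than duration ({duration})")
    t = np.arange(0.0, duration + step / 2.0, step)
    value = initial * 2.0 ** (-t / half_life)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        value = value * (1.0 + rng.normal(0.0, noise_cv, size=t.shape))
    return ProgressCurve(
        time=t,
        value=value,
        time_unit="min",
        value_name="NADH_mM",
        truth={"initial": initial, "half_life": half_life, "noise_cv": noise_cv, "seed": seed},
    )


def simulate_growth(
    lag_end: float,
    rate: float,
    carrying_capacity: float,
    duration: float,
    step: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 0.1,
) -> ProgressCurve:
    """OD600 flat at ``baseline`` until ``lag_end``, then logistic growth.

    od(t) = K*b / (b + (K-b)*exp(-rate*(t-lag_end))) for t >= lag_end, with
    additive Gaussian noise of standard deviation ``noise_sd``.
    """
    if min(lag_end, rate, carrying_capacity, duration, step, baseline) <= 0:
        raise ValueError("all growth parameters must be positive")
    if lag_end >= duration:
        raise ValueError(f"lag_end ({lag_end}) must precede duration ({duration})")
    t = np.arange(0.0, duration + step / 2.0, step)
    od = np.full_like(t, baseline)
    grow = t >= lag_end
    k, b = carrying_capacity, baseline
    od[grow] = k * b / (b + (k - b) * np.exp(-rate * (t[grow] - lag_end)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=t.shape)
    return ProgressCurve(
        time=t,
        value=od,
        time_unit="hr",
        value_name="OD600",
        truth={
            "lag_end": lag_end,
            "rate": rate,
            "carrying_capacity": carrying_capacity,
            "baseline": baseline,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
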
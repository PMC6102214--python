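"""Build C2 dimers and Cn-symmetric rings/decamers; scan the (R, D) landscape.

A ring is parameterised by two variables, following the oligomerisation model
for decameric methanol dehydrogenase:

* the rotation ("spin") angle **R** of each unit about one of its own
  principal axes, and
* the inter-unit distance **D**, measured between the centers of geometry of
  the nearest monomers of adjacent units.

Construction: the chosen principal axis of the unit is aligned to the global
z axis (the Cn axis), the unit is spun by R about z through its own center of
geometry, placed with its center at radius rho on +x, and replicated by
successive rotations of 360/n about z. The ring radius rho is not free: it is
solved by bisection so that the realised nearest-monomer distance equals the
requested D (to machine precision; the contract is 1e-3 A).

The decamer pathway is monomer -> dimer -> ring of five dimers (10 chains).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energy import DEFAULT_SETTINGS, EnergySettings, interchain_energy
from .exceptions import (
    ChainCountError,
    DegenerateGeometryError,
    EmptyInputError,
    RingGeometryError,
    TemplateError,
)
from .geometry import principal_axes, superpose
from .structio import CHAIN_ALPHABET, Structure, select_atoms

logger = logging.getLogger(__name__)

_AXIS_INDEX = {"first": 0, "second": 1, "third": 2}
_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class AssemblyParams:
    """Ring-building parameters: spin angle R (deg), neighbour distance D (A)."""

    rotation_angle_R: float
    distance_D: float
    n_units: int = 5
    rotation_axis_choice: str = "first"

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError(f"n_units must be >= 2, got {self.n_units}")
        if self.distance_D <= 0:
            raise ValueError(f"distance_D must be positive, got {self.distance_D}")
        if self.rotation_axis_choice not in _AXIS_INDEX:
            raise ValueError(
                f"rotation_axis_choice must be one of {sorted(_AXIS_INDEX)}, "
                f"got {self.rotation_axis_choice!r}"
            )
        # R is interpreted modulo 360 with 360 as the label for a full turn.
        r = float(self.rotation_angle_R) % 360.0
        self.rotation_angle_R = 360.0 if r == 0.0 else r


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping ``axis`` (unit vector) onto +z."""
    axis = axis / np.linalg.norm(axis)
    c = float(axis @ _Z)
    v = np.cross(axis, _Z)
    s = float(np.linalg.norm(v))
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def closest_axis_choice(unit: Structure, direction=(0.0, 0.0, 1.0)) -> str:
    """Which principal-axis choice ("first"/"second"/"third") best matches a direction.

    Useful to spin an assembly unit about a known symmetry axis (e.g. the C2
    axis of a dimer) regardless of how its moments happen to rank.
    """
    axes, _ = principal_axes(unit.coords)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    idx = int(np.argmax(np.abs(axes @ d)))
    return ("first", "second", "third")[idx]


def _chain_cogs(structure: Structure, coords: np.ndarray | None = None) -> np.ndarray:
    coords = structure.coords if coords is None else coords
    labels = [a.chain_id for a in structure.atoms]
    cogs = []
    for cid in structure.chains:
        mask = np.array([l == cid for l in labels])
        cogs.append(coords[mask].mean(axis=0))
    return np.array(cogs)


def _realized_neighbour_distance(chain_cogs: np.ndarray, rho: float, n_units: int) -> float:
    """Nearest chain-COG distance between adjacent units for a trial radius."""
    offset = np.array([rho, 0.0, 0.0])
    u0 = chain_cogs + offset
    u1 = u0 @ _rot_z(360.0 / n_units).T
    return float(cdist(u0, u1).min())


def _solve_ring_radius(chain_cogs: np.ndarray, n_units: int, distance_D: float) -> float:
    """Bisection for the placement radius achieving the requested neighbour distance.

    Iterated to machine precision so that symmetry-equivalent spin angles give
    bit-comparable rings.
    """
    lo, hi = distance_D / 4.0, 4.0 * distance_D
    f_lo = _realized_neighbour_distance(chain_cogs, lo, n_units) - distance_D
    f_hi = _realized_neighbour_distance(chain_cogs, hi, n_units) - distance_D
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if (f_lo > 0) == (f_hi > 0):
        raise RingGeometryError(
            f"cannot bracket requested neighbour distance {distance_D} A: "
            f"realised range [{f_lo + distance_D:.3f}, {f_hi + distance_D:.3f}] A "
            f"over radius [{lo:.3f}, {hi:.3f}] A"
        )
    mid = 0.5 * (lo + hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _realized_neighbour_distance(chain_cogs, mid, n_units) - distance_D
        if f_mid == 0.0 or (hi - lo) < 1e-13 * hi:
            break
        if (f_mid > 0) == (f_hi > 0):
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return mid


def _aligned_spun_coords(unit: Structure, params: AssemblyParams) -> np.ndarray:
    """Unit coordinates with the chosen principal axis on z, spun by R, COG at origin."""
    coords = unit.coords
    cog = coords.mean(axis=0)
    try:
        axes, _ = principal_axes(coords)
        align = _rotation_to_z(axes[_AXIS_INDEX[params.rotation_axis_choice]])
    except (EmptyInputError, DegenerateGeometryError):
        # point-like or collinear units have no meaningful spin axis; place as-is
        align = np.eye(3)
    spin = _rot_z(params.rotation_angle_R)
    # spinning about the unit's own axis then aligning it to z is the same map
    # as aligning first and spinning about z; the latter is numerically cleaner
    return (coords - cog) @ align.T @ spin.T


def build_ring(unit: Structure, params: AssemblyParams) -> Structure:
    """Cn-symmetric ring of ``params.n_units`` copies of ``unit``.

    Chains are relabelled uniquely: copy k of a unit with m chains contributes
    chains ``CHAIN_ALPHABET[k*m : (k+1)*m]``, so a ring of five 2-chain dimers
    yields chains A..J with dimer k holding chains (2k, 2k+1).
    """
    if len(unit) == 0:
        raise ValueError("cannot build a ring from an empty unit")
    local = _aligned_spun_coords(unit, params)
    local_struct = unit.with_coords(local)
    cogs = _chain_cogs(local_struct)
    rho = _solve_ring_radius(cogs, params.n_units, params.distance_D)
    offset = np.array([rho, 0.0, 0.0])

    unit_chains = unit.chains
    m = len(unit_chains)
    if params.n_units * m > len(CHAIN_ALPHABET):
        raise ValueError("too many chains for unique single-character labels")
    copies: list[Structure] = []
    for k in range(params.n_units):
        rot = _rot_z(360.0 * k / params.n_units)
        placed = (local + offset) @ rot.T
        mapping = {
            cid: CHAIN_ALPHABET[k * m + i] for i, cid in enumerate(unit_chains)
        }
        copies.append(local_struct.with_coords(placed).relabel_chains(mapping))
    return Structure.concat(
        copies,
        metadata=(
            f"C{params.n_units} ring, R={params.rotation_angle_R:g} deg, "
            f"D={params.distance_D:g} A, axis={params.rotation_axis_choice}"
        ),
    )


def build_dimer(monomer: Structure, template_dimer: Structure) -> Structure:
    """Two copies of ``monomer`` superposed onto the chains of a 2-chain template.

    Correspondence to each template chain is by C-alpha atoms in order,
    truncated to the shorter length (falls back to all atoms when either side
    has no C-alpha record). Output chains are relabelled A and B following the
    template chain order.
    """
    chains = template_dimer.chains
    if len(chains) != 2:
        raise TemplateError(
            f"dimer template must have exactly 2 chains, got {len(chains)} ({chains})"
        )
    if len(monomer) < 3:
        raise ValueError("monomer must have at least 3 atoms")

    def guide_coords(struct: Structure) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ca = select_atoms(struct, atom_names={"CA"})
        return ca.coords if len(ca) >= 3 else struct.coords

    mono_guide = guide_coords(monomer)
    parts: list[Structure] = []
    for label, cid in zip("AB", chains):
        tmpl_guide = guide_coords(template_dimer.chain(cid))
        n = min(len(mono_guide), len(tmpl_guide))
        if n < 3:
            raise TemplateError("need >= 3 corresponding atoms per template chain")
        transform, _ = superpose(mono_guide[:n], tmpl_guide[:n])
        placed = monomer.with_coords(transform.apply(monomer.coords))
        parts.append(placed.relabel_chains({c: label for c in placed.chains}))
    return Structure.concat(parts, metadata="dimer built on 2-chain template")


def build_decamer(
    dimer: Structure,
    rotation_angle_R: float,
    distance_D: float,
    rotation_axis_choice: str = "first",
) -> Structure:
    """Ring of five dimers (10 chains); D is the nearest-monomer COG distance."""
    if len(dimer.chains) != 2:
        raise ChainCountError(
            f"decamer assembly needs a 2-chain dimer, got {len(dimer.chains)} chains"
        )
    params = AssemblyParams(
        rotation_angle_R=rotation_angle_R,
        distance_D=distance_D,
        n_units=5,
        rotation_axis_choice=rotation_axis_choice,
    )
    return build_ring(dimer, params)


def junction_chain_pair(ring: Structure, units: int = 5, unit_index: int = 0) -> tuple[str, str]:
    """Closest chain pair (by chain COG) across one unit-unit junction of a ring."""
    chains = ring.chains
    m = len(chains) // units
    cogs = _chain_cogs(ring)
    a0, a1 = unit_index * m, ((unit_index + 1) % units) * m
    block = cdist(cogs[a0 : a0 + m], cogs[a1 : a1 + m])
    i, j = np.unravel_index(int(np.argmin(block)), block.shape)
    return chains[a0 + i], chains[a1 + j]


def realized_neighbour_distance(ring: Structure, units: int = 5) -> float:
    """Measure the nearest chain-COG distance between the first two units of a ring."""
    chains = ring.chains
    m = len(chains) // units
    cogs = _chain_cogs(ring)
    return float(cdist(cogs[:m], cogs[m : 2 * m]).min())


@dataclass
class EnergyLandscape:
    """Inter-chain energy over the (R, D) grid; shape len(R) x len(D)."""

    R_values: np.ndarray  # degrees
    D_values: np.ndarray  # Angstrom
    energy: np.ndarray  # kcal/mol
    params_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.R_values = np.asarray(self.R_values, dtype=float)
        self.D_values = np.asarray(self.D_values, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.shape != (len(self.R_values), len(self.D_values)):
            raise ValueError(
                f"energy shape {self.energy.shape} does not match grids "
                f"({len(self.R_values)} x {len(self.D_values)})"
            )
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("landscape energies must be finite (capping guarantees this)")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (r, d, self.energy[i, j])
            for i, r in enumerate(self.R_values)
            for j, d in enumerate(self.D_values)
        ]
        return pd.DataFrame(rows, columns=["R_deg", "D_ang", "energy_kcal_mol"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.8f")

    @classmethod
    def from_csv(cls, path) -> "EnergyLandscape":
        df = pd.read_csv(path)
        r_values = np.array(sorted(df["R_deg"].unique()))
        d_values = np.array(sorted(df["D_ang"].unique()))
        energy = (
            df.pivot(index="R_deg", columns="D_ang", values="energy_kcal_mol")
            .loc[r_values, d_values]
            .to_numpy()
        )
        return cls(r_values, d_values, energy)

    def plot_heatmap(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3.2))
        mesh = ax.pcolormesh(
            self.R_values, self.D_values, self.energy.T, shading="nearest", cmap="viridis"
        )
        fig.colorbar(mesh, ax=ax, label="inter-chain energy (kcal/mol)")
        ax.set_xlabel("rotation angle R (deg)")
        ax.set_ylabel("inter-dimer distance D (A)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def default_R_grid() -> np.ndarray:
    """2..360 degrees in 2-degree increments (180 values)."""
    return np.arange(2.0, 360.0 + 1e-9, 2.0)


def default_D_grid() -> np.ndarray:
    """40..50 Angstrom in 2-Angstrom increments (6 values)."""
    return np.arange(40.0, 50.0 + 1e-9, 2.0)


def scan_landscape(
    dimer: Structure,
    R_grid=None,
    D_grid=None,
    energy_settings: EnergySettings = DEFAULT_SETTINGS,
    rotation_axis_choice: str = "first",
    n_units: int = 5,
) -> EnergyLandscape:
    """Evaluate the inter-chain energy of the ring over the (R, D) grid.

    Evaluation is row-major (R outer, D inner). A point whose ring cannot be
    built is recorded at the per-pair cap with a warning rather than aborting.
    """
    r_values = default_R_grid() if R_grid is None else np.asarray(R_grid, dtype=float)
    d_values = default_D_grid() if D_grid is None else np.asarray(D_grid, dtype=float)
    if r_values.size == 0 or d_values.size == 0:
        raise ValueError("R and D grids must be non-empty")

    energy = np.empty((r_values.size, d_values.size))
    total = energy.size
    report_every = max(1, total // 10)
    done = 0
    for i, r in enumerate(r_values):
        for j, d in enumerate(d_values):
            try:
                ring = build_ring(
                    dimer,
                    AssemblyParams(
                        rotation_angle_R=float(r),
                        distance_D=float(d),
                        n_units=n_units,
                        rotation_axis_choice=rotation_axis_choice,
                    ),
                )
                energy[i, j] = interchain_energy(ring, energy_settings)
            except RingGeometryError as exc:
                warnings.warn(
                    f"grid point (R={r:g}, D={d:g}) failed ({exc}); recording cap",
                    stacklevel=2,
                )
                energy[i, j] = energy_settings.per_pair_cap
            done += 1
            if done % report_every == 0:
                logger.info("landscape scan: %d/%d points (%.0f%%)", done, total, 100 * done / total)
            logger.debug("E(R=%g, D=%g) = %.6f", r, d, energy[i, j])
    return EnergyLandscape(
        r_values,
        d_values,
        energy,
        params_used={
            "energy": energy_settings.to_dict(),
            "rotation_axis_choice": rotation_axis_choice,
            "n_units": n_units,
        },
    )


def find_minima(landscape: EnergyLandscape) -> list[tuple[float, float, float]]:
    """Grid-local minima as (R, D, E), global minimum first.

    A point is a minimum when its energy is <= all of its 4-neighbours; the
    angle axis wraps (360 -> first grid angle), the distance axis does not.
    Plateau ties are all reported. A perfectly flat landscape returns every
    point and emits a flatness warning.
    """
    e = landscape.energy
    n_r, n_d = e.shape
    if np.ptp(e) == 0.0:
        warnings.warn("landscape is flat: every grid point is a minimum", stacklevel=2)
    minima: list[tuple[float, float, float]] = []
    for i in range(n_r):
        for j in range(n_d):
            val = e[i, j]
            neighbours = [e[(i - 1) % n_r, j], e[(i + 1) % n_r, j]]
            if j > 0:
                neighbours.append(e[i, j - 1])
            if j < n_d - 1:
                neighbours.append(e[i, j + 1])
            if all(val <= nb for nb in neighbours):
                minima.append(
                    (float(landscape.R_values[i]), float(landscape.D_values[j]), float(val))
                )
    minima.sort(key=lambda t: (t[2], t[0], t[1]))
    return minima
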
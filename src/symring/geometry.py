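"""Rigid-body mathematics: centers, gyration, principal axes, superposition, RMSD.

All quantities are unweighted (center of geometry, not center of mass): the
assembly pipeline operates on C-alpha traces where mass weighting is moot, and
the ring parameterisation is defined in terms of centers of geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import CorrespondenceError, DegenerateGeometryError, EmptyInputError

_ONES = np.ones(3)


def _as_coords(coords, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an N x 3 coordinate array, got shape {arr.shape}")
    if arr.shape[0] < min_n:
        raise EmptyInputError(f"need at least {min_n} points, got {arr.shape[0]}")
    return arr


def center_of_geometry(coords) -> np.ndarray:
    """Unweighted mean of the coordinates (Angstrom)."""
    return _as_coords(coords).mean(axis=0)


def radius_of_gyration(coords) -> float:
    """Root-mean-square distance of the points from their center of geometry."""
    arr = _as_coords(coords)
    d2 = np.sum((arr - arr.mean(axis=0)) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def _fix_axis_sign(v: np.ndarray) -> np.ndarray:
    """Orient an axis so its dot product with (1,1,1) is non-negative.

    Exact ties are broken toward +x (then +y, then +z).
    """
    d = float(v @ _ONES)
    if d > 0:
        return v
    if d < 0:
        return -v
    for comp in v:
        if comp > 0:
            return v
        if comp < 0:
            return -v
    return v


def principal_axes(coords) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes and moments of the gyration tensor about the COG.

    Returns ``(axes, moments)`` where ``axes`` is a 3x3 array whose *rows* are
    unit vectors sorted by descending moment (eigenvalue of the per-point
    gyration tensor, A^2). Collinear or coincident point sets raise
    :class:`DegenerateGeometryError` naming the achieved rank.
    """
    arr = _as_coords(coords, min_n=3)
    centered = arr - arr.mean(axis=0)
    tensor = centered.T @ centered / arr.shape[0]
    moments, vectors = np.linalg.eigh(tensor)  # ascending
    order = np.argsort(moments)[::-1]
    moments = moments[order]
    vectors = vectors[:, order]
    scale = max(moments[0], 1e-300)
    rank = int(np.sum(moments > 1e-12 * scale))
    if rank < 2:
        raise DegenerateGeometryError(
            f"degenerate point set: gyration tensor rank {rank} (need >= 2)", rank=rank
        )
    axes = np.array([_fix_axis_sign(vectors[:, i]) for i in range(3)])
    return axes, moments


@dataclass
class RigidTransform:
    """A proper rotation followed by a translation: x -> R x + t."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # (3,), Angstrom

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        det = np.linalg.det(self.rotation)
        if err > 1e-9 or abs(det - 1.0) > 1e-9:
            raise ValueError(
                f"rotation is not proper orthonormal (orthogonality error {err:.2e}, det {det:.12f})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords) -> np.ndarray:
        arr = np.asarray(coords, dtype=float)
        return arr @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation between corresponding points (no superposition)."""
    a = _as_coords(coords_a)
    b = _as_coords(coords_b)
    if a.shape[0] != b.shape[0]:
        raise CorrespondenceError(
            f"coordinate sets differ in length: {a.shape[0]} vs {b.shape[0]}"
        )
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Correspondence is positional (point i maps to point i). The rotation is the
    Kabsch solution with a reflection guard (always a proper rotation). Returns
    the transform and the RMSD after applying it.
    """
    mob = _as_coords(mobile, min_n=3)
    ref = _as_coords(reference, min_n=3)
    if mob.shape[0] != ref.shape[0]:
        raise CorrespondenceError(
            f"coordinate sets differ in length: {mob.shape[0]} vs {ref.shape[0]}"
        )
    cm = mob.mean(axis=0)
    cr = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - cr, mob - cm)
    rmat = rot.as_matrix()
    transform = RigidTransform(rmat, cr - rmat @ cm)
    return transform, rmsd(transform.apply(mob), ref)
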
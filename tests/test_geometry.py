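"""Centers, gyration, principal axes, superposition and RMSD oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from symring import (
    RigidTransform,
    center_of_geometry,
    principal_axes,
    radius_of_gyration,
    rmsd,
    superpose,
)
from symring.exceptions import (
    CorrespondenceError,
    DegenerateGeometryError,
    EmptyInputError,
)


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return RigidTransform(rot.as_matrix(), rng.normal(0, 20, 3))


class TestCenterOfGeometry:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([[1, 2, 3]], [1, 2, 3]),
            ([[0, 0, 0], [2, 0, 0]], [1, 0, 0]),
        ],
    )
    def test_closed_form(self, points, expected):
        np.testing.assert_allclose(center_of_geometry(points), expected)

    def test_translation_equivariance(self, rng):
        pts = rng.normal(size=(40, 3))
        shift = np.array([5.0, -3.0, 11.0])
        np.testing.assert_allclose(
            center_of_geometry(pts + shift), center_of_geometry(pts) + shift, atol=1e-12
        )

    def test_empty_input_errors(self):
        with pytest.raises(EmptyInputError):
            center_of_geometry(np.empty((0, 3)))


class TestRadiusOfGyration:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([[4, 4, 4]], 0.0),
            ([[0, 0, 0], [2, 0, 0]], 1.0),
        ],
    )
    def test_closed_form(self, points, expected):
        assert radius_of_gyration(points) == pytest.approx(expected, abs=1e-12)

    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        assert radius_of_gyration(corners) == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(30, 3)) * 7
        base = radius_of_gyration(pts)
        for _ in range(5):
            moved = _random_rigid(rng).apply(pts)
            assert radius_of_gyration(moved) == pytest.approx(base, abs=1e-9)


class TestPrincipalAxes:
    def test_dominant_axis_along_x(self, rng):
        pts = np.column_stack(
            [np.linspace(-10, 10, 50), rng.normal(0, 0.01, 50), rng.normal(0, 0.005, 50)]
        )
        axes, moments = principal_axes(pts)
        np.testing.assert_allclose(np.abs(axes[0]), [1, 0, 0], atol=1e-3)
        assert axes[0] @ np.ones(3) >= 0
        assert moments[0] > 100 * moments[1]

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(size=(60, 3)) * np.array([5.0, 2.0, 1.0])
        axes, moments = principal_axes(pts)
        rot = Rotation.from_euler("zyx", [31.0, -12.0, 77.0], degrees=True).as_matrix()
        axes_rot, moments_rot = principal_axes(pts @ rot.T)
        np.testing.assert_allclose(moments_rot, moments, rtol=1e-9)
        for a, ar in zip(axes, axes_rot):
            # equal up to the sign-fixing convention
            assert min(np.linalg.norm(ar - rot @ a), np.linalg.norm(ar + rot @ a)) < 1e-9

    def test_isotropic_cloud_moments_similar(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20000, 3))
        _, moments = principal_axes(pts)
        assert moments[0] / moments[2] < 1.1

    def test_collinear_raises_with_rank(self):
        pts = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateGeometryError) as err:
            principal_axes(pts)
        assert err.value.rank == 1


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(25, 3))
        transform, value = superpose(pts, pts)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(transform.translation, 0, atol=1e-9)
        assert value < 1e-12

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(30, 3)) * 8
        rot = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        shift = np.array([4.0, -2.0, 9.0])
        moved = pts @ rot.T + shift
        transform, value = superpose(moved, pts)
        assert value < 1e-9
        np.testing.assert_allclose(transform.rotation, rot.T, atol=1e-9)

    def test_recovery_over_seeded_trials(self, rng):
        pts = rng.normal(size=(40, 3)) * 10
        worst = 0.0
        for _ in range(100):
            moved = _random_rigid(rng).apply(pts)
            _, value = superpose(moved, pts)
            worst = max(worst, value)
        assert worst < 1e-9

    def test_beats_random_placements(self, rng):
        ref = rng.normal(size=(20, 3)) * 6
        mobile = ref + rng.normal(0, 1.0, size=ref.shape)  # noisy copy
        _, optimal = superpose(mobile, ref)
        best_random = min(
            rmsd(_random_rigid(rng).apply(mobile), ref) for _ in range(1000)
        )
        assert optimal <= best_random + 1e-12

    def test_invariant_to_premotion(self, rng):
        ref = rng.normal(size=(30, 3)) * 5
        mobile = ref + rng.normal(0, 0.5, size=ref.shape)
        _, base = superpose(mobile, ref)
        for _ in range(5):
            _, moved = superpose(_random_rigid(rng).apply(mobile), ref)
            assert moved == pytest.approx(base, abs=1e-9)

    def test_returned_rmsd_consistent(self, rng):
        ref = rng.normal(size=(15, 3))
        mobile = ref + rng.normal(0, 0.3, size=ref.shape)
        transform, value = superpose(mobile, ref)
        assert rmsd(transform.apply(mobile), ref) == pytest.approx(value, abs=1e-12)

    def test_length_mismatch(self, rng):
        with pytest.raises(CorrespondenceError):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestRmsd:
    def test_identical_is_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        assert rmsd(pts, pts) == 0.0

    def test_pythagorean_shift(self, rng):
        pts = rng.normal(size=(10, 3))
        assert rmsd(pts, pts + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_metric_properties_on_seeded_triples(self, rng):
        for _ in range(20):
            a, b, c = (rng.normal(size=(8, 3)) for _ in range(3))
            assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-12)
            assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12
            assert rmsd(a, b) >= 0


class TestRigidTransform:
    def test_compose_and_inverse(self, rng):
        t1, t2 = _random_rigid(rng), _random_rigid(rng)
        pts = rng.normal(size=(12, 3))
        np.testing.assert_allclose(
            t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-9
        )
        np.testing.assert_allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-9)

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
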
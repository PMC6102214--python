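"""Dimer building, Cn ring construction, landscape scanning and minima."""

import warnings

import numpy as np
import pytest

from symring import (
    AssemblyParams,
    AtomRecord,
    EnergyLandscape,
    Structure,
    build_decamer,
    build_dimer,
    build_ring,
    find_minima,
    interchain_energy,
    realized_neighbour_distance,
    rmsd,
    scan_landscape,
)
from symring.exceptions import TemplateError

C2_Z = np.diag([-1.0, -1.0, 1.0])


def _rot_z(deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _single_atom_unit():
    return Structure([AtomRecord(1, "CA", "GLY", "A", 1, np.array([1.0, 2.0, 3.0]), "C")])


class TestBuildRing:
    def test_single_atom_pentagon_chord(self):
        ring = build_ring(
            _single_atom_unit(), AssemblyParams(rotation_angle_R=90.0, distance_D=50.0)
        )
        assert len(ring) == 5
        coords = ring.coords
        # all adjacent distances equal the requested chord
        for k in range(5):
            d = np.linalg.norm(coords[k] - coords[(k + 1) % 5])
            assert d == pytest.approx(50.0, abs=1e-3)
        # closed-form placement radius rho = D / (2 sin(pi/5))
        radii = np.linalg.norm(coords[:, :2], axis=1)
        np.testing.assert_allclose(radii, 50.0 / (2 * np.sin(np.pi / 5)), atol=1e-3)

    def test_cn_closure_is_chain_permutation(self, bundle_monomer):
        ring = build_ring(
            bundle_monomer, AssemblyParams(rotation_angle_R=70.0, distance_D=46.0)
        )
        rotated = ring.coords @ _rot_z(72.0).T
        chains = ring.chains
        # rotating by 360/5 maps unit k onto unit k+1
        n = len(bundle_monomer)
        for k in range(5):
            src = rotated[k * n : (k + 1) * n]
            dst = ring.chain(chains[(k + 1) % 5]).coords
            assert rmsd(src, dst) < 1e-6

    def test_full_turn_equals_zero_spin(self, bundle_monomer):
        full = build_ring(bundle_monomer, AssemblyParams(360.0, 44.0))
        tiny = build_ring(bundle_monomer, AssemblyParams(1e-9, 44.0))
        assert rmsd(full.coords, tiny.coords) < 1e-6

    def test_realized_distance_matches_request(self, c2_dimer):
        for d_req in (40.0, 45.0, 50.0):
            ring = build_ring(c2_dimer, AssemblyParams(33.0, d_req))
            assert realized_neighbour_distance(ring) == pytest.approx(d_req, abs=1e-3)


class TestBuildDimer:
    def test_self_template_reproduces_chain(self, c2_dimer, bundle_monomer):
        chain_a = c2_dimer.chain("A")
        built = build_dimer(chain_a, c2_dimer)
        assert built.chains == ["A", "B"]
        assert rmsd(built.chain("A").coords, chain_a.coords) < 1e-9

    def test_c2_template_yields_c2_dimer(self, c2_dimer, bundle_monomer):
        built = build_dimer(bundle_monomer, c2_dimer)
        mapped = built.chain("A").coords @ C2_Z.T
        assert rmsd(mapped, built.chain("B").coords) < 1e-6
        # and it reproduces the template itself (cross-module construction oracle)
        assert rmsd(built.coords, c2_dimer.coords) < 1e-6

    def test_swapped_template_chain_order_swaps_labels(self, c2_dimer, bundle_monomer):
        swapped_template = Structure.concat(
            [c2_dimer.chain("B"), c2_dimer.chain("A")]
        )
        built = build_dimer(bundle_monomer, swapped_template)
        direct = build_dimer(bundle_monomer, c2_dimer)
        assert rmsd(built.chain("A").coords, direct.chain("B").coords) < 1e-9
        assert rmsd(built.chain("B").coords, direct.chain("A").coords) < 1e-9

    def test_wrong_template_chain_count(self, bundle_monomer):
        with pytest.raises(TemplateError):
            build_dimer(bundle_monomer, bundle_monomer)


class TestBuildDecamer:
    def test_ten_chains_and_distance(self, c2_dimer, c2_axis_choice):
        decamer = build_decamer(c2_dimer, 120.0, 44.0, rotation_axis_choice=c2_axis_choice)
        assert decamer.chains == list("ABCDEFGHIJ")
        assert realized_neighbour_distance(decamer) == pytest.approx(44.0, abs=1e-3)

    def test_c2_spin_degeneracy_of_energy(self, c2_dimer, c2_axis_choice):
        for r in (40.0, 90.0, 137.0):
            e1 = interchain_energy(
                build_decamer(c2_dimer, r, 44.0, rotation_axis_choice=c2_axis_choice)
            )
            e2 = interchain_energy(
                build_decamer(c2_dimer, r + 180.0, 44.0, rotation_axis_choice=c2_axis_choice)
            )
            assert e1 == pytest.approx(e2, abs=1e-6)


class TestScanLandscape:
    def test_grid_shape_and_default_ranges(self):
        from symring import default_D_grid, default_R_grid

        r_grid, d_grid = default_R_grid(), default_D_grid()
        assert len(r_grid) == 180 and r_grid[0] == 2.0 and r_grid[-1] == 360.0
        assert len(d_grid) == 6 and d_grid[0] == 40.0 and d_grid[-1] == 50.0

    def test_single_point_matches_direct_call(self, c2_dimer, c2_axis_choice):
        landscape = scan_landscape(
            c2_dimer, R_grid=[100.0], D_grid=[46.0], rotation_axis_choice=c2_axis_choice
        )
        assert landscape.energy.shape == (1, 1)
        direct = interchain_energy(
            build_decamer(c2_dimer, 100.0, 46.0, rotation_axis_choice=c2_axis_choice)
        )
        assert landscape.energy[0, 0] == pytest.approx(direct, abs=1e-9)

    def test_c2_symmetry_on_coarse_grid(self, c2_dimer, c2_axis_choice):
        r_grid = [30.0, 90.0, 150.0, 210.0, 270.0, 330.0]
        landscape = scan_landscape(
            c2_dimer, R_grid=r_grid, D_grid=[44.0], rotation_axis_choice=c2_axis_choice
        )
        e = landscape.energy[:, 0]
        np.testing.assert_allclose(e[:3], e[3:], atol=1e-6)

    def test_clash_regime_at_short_distance(self, c2_dimer, c2_axis_choice):
        landscape = scan_landscape(
            c2_dimer,
            R_grid=np.arange(20.0, 361.0, 20.0),
            D_grid=[40.0, 50.0],
            rotation_axis_choice=c2_axis_choice,
        )
        mean_by_d = landscape.energy.mean(axis=0)
        assert mean_by_d[0] >= mean_by_d[1]

    def test_csv_round_trip(self, tmp_path, c2_dimer, c2_axis_choice):
        landscape = scan_landscape(
            c2_dimer, R_grid=[90.0, 180.0], D_grid=[44.0, 48.0],
            rotation_axis_choice=c2_axis_choice,
        )
        path = tmp_path / "landscape.csv"
        landscape.to_csv(path)
        loaded = EnergyLandscape.from_csv(path)
        np.testing.assert_allclose(loaded.energy, landscape.energy, atol=1e-6)


class TestFindMinima:
    def _landscape(self, energy, r=None, d=None):
        energy = np.asarray(energy, dtype=float)
        r = np.arange(energy.shape[0], dtype=float) + 1 if r is None else r
        d = np.arange(energy.shape[1], dtype=float) + 40 if d is None else d
        return EnergyLandscape(r, d, energy)

    def test_unique_global_minimum_first(self):
        e = np.ones((6, 3))
        e[4, 1] = -5.0
        e[2, 0] = -1.0
        minima = find_minima(self._landscape(e))
        assert minima[0] == (5.0, 41.0, -5.0)

    def test_flat_landscape_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            minima = find_minima(self._landscape(np.zeros((4, 2))))
        assert len(minima) == 8

    def test_cosine_double_well(self):
        r_values = np.arange(2.0, 360.1, 2.0)
        d_values = np.array([40.0, 44.0, 48.0])
        energy = np.cos(2 * np.radians(r_values))[:, None] * np.ones((1, 3))
        minima = find_minima(self._landscape(energy, r_values, d_values))
        assert {m[0] for m in minima} == {90.0, 270.0}
        assert len(minima) == 6  # both wells at every distance

    def test_angle_axis_wraps(self):
        # last row is a minimum only because the angle axis wraps onto row 0
        e = np.array([[3.0], [1.0], [2.0], [3.0], [4.0], [3.0], [2.0], [0.5]])
        minima = find_minima(self._landscape(e))
        assert {m[0] for m in minima} == {2.0, 8.0}
        assert minima[0][0] == 8.0  # global minimum first
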
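import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lrip.energetics import (
    GBSettings,
    _hct_descreen_term,
    coulomb_pair,
    decompose_ligand_residue,
    effective_born_radii,
    gb_polar_energy,
    lj_pair,
    sasa,
)
from lrip.synthetic import ToyComplexSpec, make_toy_complex

from .oracles import (
    born_radii_quad,
    coulomb_scalar,
    descreen_integral_quad,
    lj_scalar,
    sasa_sphere_closed_form,
)


class TestCoulombPair:
    def test_zero_charge(self):
        assert coulomb_pair(0.0, 0.7, 3.0) == 0.0

    def test_unit_charges_unit_distance(self):
        assert coulomb_pair(1.0, 1.0, 1.0, eps_in=1.0) == pytest.approx(332.0636)

    def test_antisymmetry_in_sign(self):
        assert coulomb_pair(0.5, -0.5, 2.0) == -coulomb_pair(0.5, 0.5, 2.0)

    def test_symmetry_under_swap(self):
        assert coulomb_pair(0.3, -0.8, 4.2) == coulomb_pair(-0.8, 0.3, 4.2)

    def test_zero_distance_raises(self):
        with pytest.raises(ValueError):
            coulomb_pair(1.0, 1.0, 0.0)


class TestLJPair:
    def test_minimum_at_rmin(self):
        # at rij = Rmin the well depth is exactly -eps_ij
        e = lj_pair(1.7, 0.1, 1.9, 0.2, 1.7 + 1.9)
        assert e == pytest.approx(-math.sqrt(0.1 * 0.2), abs=1e-12)

    def test_zero_epsilon(self):
        assert lj_pair(1.7, 0.0, 1.9, 0.3, 2.5) == 0.0

    def test_zero_crossing(self):
        # E = 0 where (Rmin/r)^6 = 2, i.e. r = Rmin * 2^(-1/6)
        rmin = 3.4
        r0 = rmin * 2 ** (-1 / 6)
        assert lj_pair(1.7, 0.15, 1.7, 0.15, r0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_distance_raises(self):
        with pytest.raises(ValueError):
            lj_pair(1.7, 0.1, 1.7, 0.1, 0.0)


class TestEffectiveBornRadii:
    def test_isolated_atom_keeps_intrinsic_radius(self):
        r = effective_born_radii(np.zeros((1, 3)), np.array([1.5]), np.array([0.8]))
        assert r[0] == pytest.approx(1.5, abs=1e-12)

    def test_distant_pair_approaches_intrinsic(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        r = effective_born_radii(coords, np.array([1.5, 1.5]), np.array([0.8, 0.8]))
        assert np.allclose(r, 1.5, atol=1e-6)

    def test_close_pair_grows_radius(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        r = effective_born_radii(coords, np.array([1.5, 1.5]), np.array([0.8, 0.8]))
        assert np.all(r > 1.5)

    @pytest.mark.parametrize(
        "rho_i,r,s_j",
        [
            (1.5, 3.0, 1.2),  # separated spheres
            (1.5, 2.0, 1.2),  # overlapping
            (1.5, 1.0, 1.2),  # deep overlap, L = rho_i
            (0.8, 0.5, 2.0),  # atom i engulfed by scaled sphere j
            (1.5, 5.0, 1.2),  # well separated
        ],
    )
    def test_descreen_term_matches_quadrature(self, rho_i, r, s_j):
        analytic = _hct_descreen_term(rho_i, r, s_j)
        numeric = descreen_integral_quad(rho_i, r, s_j)
        assert analytic == pytest.approx(numeric, abs=1e-9)

    def test_cluster_radii_match_quadrature_oracle(self, rng):
        n = 5
        coords = rng.uniform(-2.5, 2.5, size=(n, 3))
        rho = rng.uniform(1.2, 1.8, size=n)
        screen = rng.uniform(0.7, 0.9, size=n)
        expected = born_radii_quad(coords, rho, screen)
        actual = effective_born_radii(coords, rho, screen)
        assert np.allclose(actual, expected, atol=1e-6)


class TestGBPolar:
    def test_born_ion_closed_form(self):
        total, _ = gb_polar_energy(
            np.zeros((1, 3)), np.array([1.0]), np.array([2.0]), np.array([0.8])
        )
        expected = -332.0636 / 2.0 * (1.0 - 1.0 / 78.5) / 2.0
        assert total == pytest.approx(expected, abs=1e-6)

    def test_zero_charges(self, rng):
        coords = rng.uniform(-3, 3, size=(4, 3))
        total, matrix = gb_polar_energy(
            coords, np.zeros(4), np.full(4, 1.5), np.full(4, 0.8)
        )
        assert total == 0.0
        assert np.all(matrix == 0.0)

    def test_no_dielectric_contrast(self, rng):
        coords = rng.uniform(-3, 3, size=(4, 3))
        q = rng.uniform(-0.5, 0.5, size=4)
        settings = GBSettings(eps_in=1.0, eps_out=1.0 + 1e-12)
        total, _ = gb_polar_energy(
            coords, q, np.full(4, 1.5), np.full(4, 0.8), settings
        )
        assert abs(total) < 1e-9

    def test_matrix_symmetric_and_consistent_with_total(self, rng):
        coords = rng.uniform(-4, 4, size=(6, 3))
        q = rng.uniform(-0.5, 0.5, size=6)
        total, m = gb_polar_energy(coords, q, np.full(6, 1.5), np.full(6, 0.8))
        assert np.allclose(m, m.T, atol=1e-12)
        assert total == pytest.approx(np.trace(m) + np.triu(m, 1).sum(), abs=1e-9)

    def test_rotation_translation_invariance(self, rng):
        coords = rng.uniform(-4, 4, size=(6, 3))
        q = rng.uniform(-0.5, 0.5, size=6)
        rho = np.full(6, 1.5)
        screen = np.full(6, 0.8)
        e0, _ = gb_polar_energy(coords, q, rho, screen)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -5.0, 3.0])
        e1, _ = gb_polar_energy(moved, q, rho, screen)
        assert e1 == pytest.approx(e0, abs=1e-6)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        area = sasa(np.zeros((1, 3)), np.array([1.5]), probe_radius=1.4)
        expected = sasa_sphere_closed_form(1.5, 1.4)
        assert area[0] == pytest.approx(expected, rel=0.01)

    def test_distant_spheres_unoccluded(self):
        coords = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        areas = sasa(coords, np.array([1.5, 2.0]), probe_radius=1.4)
        assert areas[0] == pytest.approx(sasa_sphere_closed_form(1.5, 1.4), rel=0.01)
        assert areas[1] == pytest.approx(sasa_sphere_closed_form(2.0, 1.4), rel=0.01)

    def test_buried_atom_has_zero_area(self):
        # a small atom fully inside a much larger one
        coords = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        areas = sasa(coords, np.array([1.0, 10.0]), probe_radius=1.4, sasa_points=2000)
        assert areas[0] == 0.0

    def test_deterministic(self, rng):
        coords = rng.uniform(-3, 3, size=(5, 3))
        radii = rng.uniform(1.2, 1.8, size=5)
        a1 = sasa(coords, radii)
        a2 = sasa(coords, radii)
        assert np.array_equal(a1, a2)

    def test_lattice_convergence(self):
        expected = sasa_sphere_closed_form(1.5, 1.4)
        errors = [
            abs(sasa(np.zeros((1, 3)), np.array([1.5]), sasa_points=n)[0] - expected)
            for n in (60, 960, 8000)
        ]
        assert errors[2] <= errors[0]


class TestDecomposition:
    def test_zero_interaction_gives_zero_rows(self, toy_spec):
        ensemble = make_toy_complex(toy_spec)
        for aid in ensemble.params.charge:
            ensemble.params.charge[aid] = 0.0
            ensemble.params.lj_epsilon[aid] = 0.0
        rows = decompose_ligand_residue(ensemble, include_nonpolar=False)
        for snapshot_rows in rows:
            for row in snapshot_rows:
                assert row.total == pytest.approx(0.0, abs=1e-12)

    def test_two_body_system(self):
        from lrip.complex_io import (
            AtomRecord,
            ConformationEnsemble,
            ForceFieldParameters,
            ResidueLabelMap,
        )

        atoms = [
            AtomRecord(1, "L1", ("L", 1, "LIG"), "ligand"),
            AtomRecord(2, "A1", ("A", 1, "TOY"), "receptor"),
        ]
        coords = np.array([[[0.0, 0.0, 0.0], [3.5, 0.0, 0.0]]])
        params = ForceFieldParameters(
            charge={1: 0.3, 2: -0.4},
            lj_rmin_half={1: 1.7, 2: 1.9},
            lj_epsilon={1: 0.1, 2: 0.2},
            gb_radius={1: 1.5, 2: 1.6},
            gb_screen={1: 0.8, 2: 0.85},
            atom_type={1: "LT", 2: "RT"},
        )
        labels = ResidueLabelMap(labels={("A", 1, "TOY"): "R1"}, ligand_resname="LIG")
        ensemble = ConformationEnsemble(
            atoms=atoms, snapshots=coords, params=params, labels=labels
        )
        rows = decompose_ligand_residue(ensemble)[0]
        assert len(rows) == 1
        row = rows[0]
        assert row.ele == pytest.approx(coulomb_scalar(0.3, -0.4, 3.5), abs=1e-9)
        assert row.vdw == pytest.approx(lj_scalar(1.7, 0.1, 1.9, 0.2, 3.5), abs=1e-9)
        # GB cross term: full unordered pair term between the two atoms
        reff = effective_born_radii(
            coords[0], np.array([1.5, 1.6]), np.array([0.8, 0.85])
        )
        fgb = math.sqrt(
            3.5**2 + reff[0] * reff[1] * math.exp(-(3.5**2) / (4 * reff[0] * reff[1]))
        )
        expected_gb = -332.0636 * (1 - 1 / 78.5) * 0.3 * -0.4 / fgb
        assert row.gb_polar == pytest.approx(expected_gb, abs=1e-9)

    def test_conservation_against_double_loop(self, toy_ensemble):
        rows = decompose_ligand_residue(toy_ensemble)
        q, rmh, eps = {}, {}, {}
        p = toy_ensemble.params
        lig = [i for i, a in enumerate(toy_ensemble.atoms) if a.segment == "ligand"]
        rec = [i for i, a in enumerate(toy_ensemble.atoms) if a.segment == "receptor"]
        ids = [a.atom_id for a in toy_ensemble.atoms]
        for snap_idx, coords in enumerate(toy_ensemble.snapshots):
            total_ele = total_vdw = 0.0
            for i in lig:
                for j in rec:
                    rij = math.dist(coords[i], coords[j])
                    total_ele += coulomb_scalar(
                        p.charge[ids[i]], p.charge[ids[j]], rij
                    )
                    total_vdw += lj_scalar(
                        p.lj_rmin_half[ids[i]],
                        p.lj_epsilon[ids[i]],
                        p.lj_rmin_half[ids[j]],
                        p.lj_epsilon[ids[j]],
                        rij,
                    )
            decomposed_ele = sum(r.ele for r in rows[snap_idx])
            decomposed_vdw = sum(r.vdw for r in rows[snap_idx])
            assert decomposed_ele == pytest.approx(total_ele, abs=1e-6)
            assert decomposed_vdw == pytest.approx(total_vdw, abs=1e-6)

    def test_gb_cross_conservation(self, toy_ensemble):
        rows = decompose_ligand_residue(toy_ensemble)
        q = np.array(
            [toy_ensemble.params.charge[a.atom_id] for a in toy_ensemble.atoms]
        )
        rho = np.array(
            [toy_ensemble.params.gb_radius[a.atom_id] for a in toy_ensemble.atoms]
        )
        screen = np.array(
            [toy_ensemble.params.gb_screen[a.atom_id] for a in toy_ensemble.atoms]
        )
        lig = toy_ensemble.ligand_mask
        for snap_idx, coords in enumerate(toy_ensemble.snapshots):
            _, matrix = gb_polar_energy(coords, q, rho, screen)
            cross = matrix[np.ix_(lig, ~lig)].sum()
            decomposed = sum(r.gb_polar for r in rows[snap_idx])
            assert decomposed == pytest.approx(cross, abs=1e-6)

    def test_empty_ligand_raises(self, toy_ensemble):
        from dataclasses import replace

        from lrip.complex_io import ConformationEnsemble

        atoms = [
            replace(a, segment="receptor") if a.segment == "ligand" else a
            for a in toy_ensemble.atoms
        ]
        ensemble = ConformationEnsemble(
            atoms=atoms,
            snapshots=toy_ensemble.snapshots,
            params=toy_ensemble.params,
            labels=toy_ensemble.labels,
        )
        with pytest.raises(ValueError, match="ligand"):
            decompose_ligand_residue(ensemble)

    def test_rigid_motion_invariance(self, toy_ensemble):
        from lrip.complex_io import ConformationEnsemble

        rot = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = ConformationEnsemble(
            atoms=toy_ensemble.atoms,
            snapshots=toy_ensemble.snapshots @ rot.T + np.array([5.0, 5.0, -2.0]),
            params=toy_ensemble.params,
            labels=toy_ensemble.labels,
        )
        rows0 = decompose_ligand_residue(toy_ensemble)[0]
        rows1 = decompose_ligand_residue(moved)[0]
        for a, b in zip(rows0, rows1):
            assert b.total == pytest.approx(a.total, abs=1e-6)

    def test_nonpolar_term_enabled(self, toy_ensemble):
        rows = decompose_ligand_residue(toy_ensemble, include_nonpolar=True)
        # receptor residues lose accessible area when the ligand is present
        assert any(r.nonpolar != 0.0 for r in rows[0])
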
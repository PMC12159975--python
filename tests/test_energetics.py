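"""Nonbonded energy engine: pair terms, group sums, residue decomposition,
ensemble statistics, SASA."""

import math

import numpy as np
import pytest

from gluecoop.constants import COULOMB_CONSTANT, NONPOLAR_GAMMA
from gluecoop.energetics import (
    AtomRecord,
    Ensemble,
    ParameterizedComplex,
    ensemble_interaction_energy,
    group_interaction_energy,
    nonpolar_solvation,
    pair_nonbonded_energy,
    residue_level_profile,
    sasa,
    trajectory_statistics,
)
from gluecoop.synthetic import (
    ToyComplexSpec,
    make_toy_ternary_system,
    reference_group_energies,
    sample_ensemble,
)

from conftest import random_rotation


def atom(serial, comp, xyz, q=0.0, eps=0.0, rmin_half=1.0, res=1,
         radius=1.7):
    return AtomRecord(
        atom_id=serial, atom_name=f"X{serial}", residue_index=res,
        residue_name="RES", component_label=comp, coordinates=tuple(xyz),
        partial_charge=q, lj_epsilon=eps, lj_rmin_half=rmin_half, mass=12.0,
        vdw_radius_for_sasa=radius,
    )


class TestPairEnergy:
    def test_unit_opposite_charges_at_one_angstrom(self):
        pe = pair_nonbonded_energy(
            atom(1, "A", (0, 0, 0), q=1.0), atom(2, "L", (1, 0, 0), q=-1.0)
        )
        assert pe.elec == -COULOMB_CONSTANT / 2.0
        assert pe.vdw == 0.0

    def test_lj_minimum_depth_and_curvature(self):
        a = atom(1, "A", (0, 0, 0), eps=0.15, rmin_half=1.7)
        rmin = 3.4
        b_at = lambda r: atom(2, "L", (r, 0, 0), eps=0.15, rmin_half=1.7)
        assert pair_nonbonded_energy(a, b_at(rmin)).vdw == pytest.approx(
            -0.15, abs=1e-14
        )
        # derivative changes sign at the minimum
        h = 1e-4
        below = pair_nonbonded_energy(a, b_at(rmin - h)).vdw
        above = pair_nonbonded_energy(a, b_at(rmin + h)).vdw
        assert below > -0.15 and above > -0.15

    def test_dielectric_modes_differ_by_one_power_of_r(self):
        a = atom(1, "A", (0, 0, 0), q=0.5)
        b = atom(2, "L", (4, 0, 0), q=-0.3)
        e_2r = pair_nonbonded_energy(a, b, dielectric="2r").elec
        e_c2 = pair_nonbonded_energy(a, b, dielectric="const2").elec
        assert e_c2 == pytest.approx(e_2r * 4.0, rel=1e-12)

    def test_random_pairs_match_independent_scalar_formula(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            q1, q2 = rng.uniform(-1, 1, 2)
            e1, e2 = rng.uniform(0.01, 0.3, 2)
            rh1, rh2 = rng.uniform(1.0, 2.0, 2)
            r = rng.uniform(1.5, 12.0)
            pe = pair_nonbonded_energy(
                atom(1, "A", (0, 0, 0), q=q1, eps=e1, rmin_half=rh1),
                atom(2, "L", (r, 0, 0), q=q2, eps=e2, rmin_half=rh2),
            )
            # spreadsheet-style re-evaluation
            elec = 332.0636 * q1 * q2 / (2 * r**2)
            rmin = rh1 + rh2
            vdw = math.sqrt(e1 * e2) * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            assert pe.elec == pytest.approx(elec, abs=1e-12)
            assert pe.vdw == pytest.approx(vdw, abs=1e-12)

    def test_overlapping_atoms_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pair_nonbonded_energy(atom(1, "A", (0, 0, 0)), atom(2, "L", (0, 0, 0)))


class TestGroupEnergy:
    def test_singleton_groups_equal_pair_energy(self):
        a = atom(1, "A", (0, 0, 0), q=0.4, eps=0.1)
        b = atom(2, "L", (3, 0, 0), q=-0.2, eps=0.2)
        cx = ParameterizedComplex([a, b])
        e, v, tot = group_interaction_energy(cx.coordinates, cx, "AL")
        pe = pair_nonbonded_energy(a, b)
        assert (e, v) == pytest.approx((pe.elec, pe.vdw), abs=1e-14)
        assert tot == e + v

    def test_bilinearity_in_charges(self, toy_complex):
        cx, _ = toy_complex
        e1, v1, _ = group_interaction_energy(cx.coordinates, cx, "AL")
        doubled = ParameterizedComplex([
            AtomRecord(**{**a.__dict__, "partial_charge": 2 * a.partial_charge})
            for a in cx.atoms
        ])
        e2, v2, _ = group_interaction_energy(doubled.coordinates, doubled, "AL")
        assert e2 == pytest.approx(4 * e1, rel=1e-12)
        assert v2 == pytest.approx(v1, rel=1e-12)

    @pytest.mark.parametrize("pair", ["AL", "LB", "AB"])
    def test_matches_brute_force_oracle(self, toy_complex, pair):
        cx, truth = toy_complex
        e, v, _ = group_interaction_energy(cx.coordinates, cx, pair)
        te, tv = truth.pair_totals[pair]
        assert e == pytest.approx(te, abs=1e-10)
        assert v == pytest.approx(tv, abs=1e-10)

    def test_elec_scales_as_r_minus_2(self):
        # halving all distances quadruples elec under eps(r) = 2r, and only
        # doubles it under constant eps = 2
        a = atom(1, "A", (0, 0, 0), q=0.7)
        b = atom(2, "L", (6, 0, 0), q=-0.7)
        cx = ParameterizedComplex([a, b])
        e_full, _, _ = group_interaction_energy(cx.coordinates, cx, "AL")
        e_half, _, _ = group_interaction_energy(cx.coordinates * 0.5, cx, "AL")
        assert e_half == pytest.approx(4 * e_full, rel=1e-12)
        c_full, _, _ = group_interaction_energy(cx.coordinates, cx, "AL",
                                                dielectric="const2")
        c_half, _, _ = group_interaction_energy(cx.coordinates * 0.5, cx, "AL",
                                                dielectric="const2")
        assert c_half == pytest.approx(2 * c_full, rel=1e-12)

    def test_rigid_body_invariance(self, toy_complex):
        cx, _ = toy_complex
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        moved = cx.coordinates @ rot.T + np.array([10.0, -3.0, 7.0])
        for pair in ("AL", "LB", "AB"):
            ref = group_interaction_energy(cx.coordinates, cx, pair)
            got = group_interaction_energy(moved, cx, pair)
            assert got == pytest.approx(ref, abs=1e-9)

    def test_cutoff_drops_distant_pairs(self):
        a = atom(1, "A", (0, 0, 0), q=1.0)
        b = atom(2, "L", (3, 0, 0), q=-1.0)
        c = atom(3, "L", (30, 0, 0), q=-1.0, res=2)
        cx = ParameterizedComplex([a, b, c])
        e_all, _, _ = group_interaction_energy(cx.coordinates, cx, "AL")
        e_cut, _, _ = group_interaction_energy(cx.coordinates, cx, "AL",
                                               cutoff=12.0)
        only_near = pair_nonbonded_energy(a, b).elec
        assert e_cut == pytest.approx(only_near, abs=1e-14)
        assert e_all != pytest.approx(only_near, abs=1e-6)

    def test_empty_group_rejected(self):
        cx = ParameterizedComplex([atom(1, "A", (0, 0, 0)), atom(2, "L", (3, 0, 0))])
        with pytest.raises(ValueError, match="empty"):
            group_interaction_energy(cx.coordinates, cx, "LB")


class TestResidueProfile:
    def test_single_residue_partner_equals_group_statistics(self):
        atoms = [atom(1, "L", (0, 0, 0), q=0.5),
                 atom(2, "A", (4, 0, 0), q=-0.3, res=7),
                 atom(3, "A", (5, 1, 0), q=0.1, res=7)]
        cx = ParameterizedComplex(atoms)
        ens = sample_ensemble(cx, 10, 0.05, seed=21)
        profile = residue_level_profile(ens, "L", "A")
        assert len(profile) == 1
        report = ensemble_interaction_energy(ens, "AL")
        assert profile["total_mean"].iloc[0] == pytest.approx(report.total.mean,
                                                              abs=1e-12)
        assert profile["total_std"].iloc[0] == pytest.approx(
            report.total.sample_std, abs=1e-12
        )

    def test_planted_dominant_residue_ranks_first(self):
        spec = ToyComplexSpec(seed=8, salt_bridge="AL")
        cx, truth = make_toy_ternary_system(spec)
        profile = residue_level_profile(Ensemble.single_frame(cx), "L", "A")
        by_elec = profile.sort_values("elec_mean")
        # ground truth: residue ordering by the generator's scalar loop
        truth_res = truth.per_residue[("AL", "A")]
        expected_first = min(truth_res, key=lambda k: truth_res[k][0])
        assert by_elec["residue_index"].iloc[0] == expected_first

    def test_additivity_partition(self, toy_complex, noisy_ensemble):
        for partner, ligand in [("A", "L"), ("B", "L")]:
            pair = "AL" if partner == "A" else "LB"
            profile = residue_level_profile(noisy_ensemble, ligand, partner)
            report = ensemble_interaction_energy(noisy_ensemble, pair)
            assert profile["total_mean"].sum() == pytest.approx(
                report.total.mean, abs=1e-9
            )

    def test_matches_generator_ground_truth_per_residue(self, toy_complex):
        cx, truth = toy_complex
        profile = residue_level_profile(Ensemble.single_frame(cx), "L", "A")
        for _, row in profile.iterrows():
            te, tv = truth.per_residue[("AL", "A")][row["residue_index"]]
            assert row["elec_mean"] == pytest.approx(te, abs=1e-10)
            assert row["vdw_mean"] == pytest.approx(tv, abs=1e-10)


class TestTrajectoryStatistics:
    def test_constant_series(self):
        stats = trajectory_statistics([2.5] * 8)
        assert stats.mean == 2.5 and stats.sample_std == 0.0

    def test_two_point_closed_form(self):
        stats = trajectory_statistics([1.0, 3.0])
        assert stats.mean == 2.0
        assert stats.sample_std == pytest.approx(math.sqrt(2.0), rel=1e-14)

    def test_single_frame_flagged_zero_std(self):
        stats = trajectory_statistics([4.2])
        assert stats.n_frames == 1 and stats.sample_std == 0.0
        assert stats.std_error == 0.0

    def test_gaussian_series_matches_two_pass_computation(self):
        rng = np.random.default_rng(99)
        xs = rng.normal(2.0, 3.0, 1000)
        stats = trajectory_statistics(xs)
        mean = sum(xs) / len(xs)
        var = sum((x - mean) ** 2 for x in xs) / (len(xs) - 1)
        assert stats.mean == pytest.approx(mean, abs=1e-12)
        assert stats.sample_std == pytest.approx(math.sqrt(var), abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            trajectory_statistics([])


class TestSasa:
    def test_single_atom_converges_to_sphere_area(self):
        cx = ParameterizedComplex([atom(1, "A", (0, 0, 0), radius=1.6)])
        analytic = 4 * math.pi * (1.6 + 1.4) ** 2
        assert sasa(cx, n_sphere_points=960) == pytest.approx(analytic, rel=1e-2)
        coarse = abs(sasa(cx, n_sphere_points=100) - analytic)
        fine = abs(sasa(cx, n_sphere_points=4000) - analytic)
        assert fine <= coarse + 1e-9

    def test_coincident_atoms_counted_once(self):
        single = ParameterizedComplex([atom(1, "A", (0, 0, 0), radius=1.6)])
        double = ParameterizedComplex([
            atom(1, "A", (0, 0, 0), radius=1.6),
            atom(2, "A", (0, 0, 0), radius=1.6),
        ])
        assert sasa(double, n_sphere_points=960) == pytest.approx(
            sasa(single, n_sphere_points=960), abs=1e-9
        )

    def test_buried_atom_contributes_nothing(self):
        cx = ParameterizedComplex([
            atom(1, "A", (0, 0, 0), radius=5.0),
            atom(2, "A", (0, 0, 0.5), radius=0.5, res=2),
        ])
        only_big = ParameterizedComplex([atom(1, "A", (0, 0, 0), radius=5.0)])
        assert sasa(cx, n_sphere_points=960) == pytest.approx(
            sasa(only_big, n_sphere_points=960), rel=1e-9
        )

    def test_rigid_body_invariance(self, toy_complex):
        cx, _ = toy_complex
        rng = np.random.default_rng(31)
        rot = random_rotation(rng)
        moved = cx.coordinates @ rot.T + np.array([5.0, 5.0, -2.0])
        ref = sasa(cx, n_sphere_points=500)
        got = sasa(cx, n_sphere_points=500, coordinates=moved)
        assert got == pytest.approx(ref, abs=1e-9 * max(1.0, ref))

    def test_cross_check_against_biotite(self, toy_complex):
        struc = pytest.importorskip("biotite.structure")
        cx, _ = toy_complex
        arr = struc.AtomArray(len(cx))
        arr.coord = cx.coordinates.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * len(cx)))
        ref = float(struc.sasa(arr, probe_radius=1.4, point_number=2000,
                               vdw_radii=cx.sasa_radii).sum())
        got = sasa(cx, n_sphere_points=2000)
        assert got == pytest.approx(ref, rel=2e-2)

    def test_nonpolar_solvation_uses_gamma(self):
        assert nonpolar_solvation(100.0) == pytest.approx(0.72, abs=1e-12)
        assert nonpolar_solvation(0.0) == 0.0
        assert NONPOLAR_GAMMA == 0.0072
        with pytest.raises(ValueError):
            nonpolar_solvation(-1.0)

    def test_min_points_enforced(self):
        cx = ParameterizedComplex([atom(1, "A", (0, 0, 0))])
        with pytest.raises(ValueError, match="sphere"):
            sasa(cx, n_sphere_points=50)
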
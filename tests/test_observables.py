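"""Membrane observables: arithmetic identities, analytic oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import membranekit as mk
from membranekit.constants import CM2_PER_S_PER_NM2_PER_PS
from membranekit.observables import _msd_time_origin_average
from membranekit.trajectory import LabeledTrajectory


def _minimal_traj(positions, roles, leaflets, box=(10.0, 10.0, 10.0),
                  mol_ids=None, masses=None, dt=1.0):
    """Hand-built trajectory: positions (F, N, 3)."""
    positions = np.asarray(positions, dtype=float)
    F, N, _ = positions.shape
    return LabeledTrajectory(
        time=dt * np.arange(F),
        box=np.tile(box, (F, 1)),
        molecule_id=np.asarray(mol_ids if mol_ids is not None else np.arange(N)),
        role=np.asarray(roles, dtype=object),
        leaflet=np.asarray(leaflets, dtype=object),
        mass=np.asarray(masses if masses is not None else np.ones(N), dtype=float),
        positions=positions,
    )


class TestAreaPerLipid:
    def test_arithmetic(self):
        traj = _minimal_traj(np.zeros((3, 1, 3)), ["P"], ["upper"], box=(6.3, 6.4, 8))
        r = mk.area_per_lipid(traj, 64)
        assert r.mean == pytest.approx(6.3 * 6.4 / 64)
        assert r.sd == 0.0  # constant box


class TestThickness:
    def test_fixed_planes(self):
        pos = np.zeros((4, 2, 3))
        pos[:, 0, 2] = 2.02
        pos[:, 1, 2] = -2.02
        traj = _minimal_traj(pos, ["P", "P"], ["upper", "lower"])
        r = mk.membrane_thickness(traj)
        assert r.mean == pytest.approx(4.04)
        assert r.sd == pytest.approx(0.0)

    def test_symmetric_noise_unbiased(self):
        rng = np.random.default_rng(0)
        n = 2000
        pos = np.zeros((n, 2, 3))
        pos[:, 0, 2] = 2.0 + rng.normal(0, 0.1, n)
        pos[:, 1, 2] = -2.0 + rng.normal(0, 0.1, n)
        traj = _minimal_traj(pos, ["P", "P"], ["upper", "lower"])
        assert mk.membrane_thickness(traj).mean == pytest.approx(4.0, abs=0.02)

    def test_thinner_membrane_ordering_preserved(self):
        thick = mk.gen_bilayer_trajectory(mk.BilayerSpec(
            n_lipids_per_leaflet=8, n_solutes=0, n_frames=50,
            target_thickness=4.04, target_scd=(0.14,), seed=1))
        thin = mk.gen_bilayer_trajectory(mk.BilayerSpec(
            n_lipids_per_leaflet=8, n_solutes=0, n_frames=50,
            target_thickness=3.81, target_scd=(0.20,), seed=1))
        assert mk.membrane_thickness(thin).mean < mk.membrane_thickness(thick).mean

    def test_missing_leaflet_rejected(self):
        traj = _minimal_traj(np.zeros((2, 1, 3)), ["P"], ["upper"])
        with pytest.raises(ValueError):
            mk.membrane_thickness(traj)


class TestOrderParameters:
    @pytest.mark.parametrize(
        "cos2,expected",
        [
            (0.0, -0.5),          # bond perpendicular to the normal: all-trans
            (1.0 / 3.0, 0.0),     # magic angle 54.7356 deg
            (0.24, -0.14),        # analytic inversion of the formula
            (1.0, 1.0),           # bond along the normal
        ],
    )
    def test_analytic_angles(self, cos2, expected):
        ct = np.sqrt(cos2)
        stheta = np.sqrt(1 - cos2)
        pos = np.zeros((2, 2, 3))
        pos[:, 1] = [0.109 * stheta, 0.0, 0.109 * ct]  # H relative to C at origin
        traj = _minimal_traj(pos, ["CD_C_2", "CD_H_2"], ["upper", "upper"],
                             mol_ids=[0, 0])
        prof = mk.order_parameters(traj)
        assert prof.s_cd[0] == pytest.approx(expected, abs=1e-12)
        assert prof.s_cd_abs[0] == pytest.approx(abs(expected), abs=1e-12)

    def test_generated_trajectory_recovers_targets(self, small_traj):
        prof = mk.order_parameters(small_traj)
        np.testing.assert_allclose(prof.s_cd, [-0.14, -0.14, -0.14], atol=1e-9)

    def test_missing_partner_rejected(self):
        traj = _minimal_traj(np.zeros((1, 1, 3)), ["CD_C_2"], ["upper"])
        with pytest.raises(ValueError, match="missing"):
            mk.order_parameters(traj)

    def test_scd_bounds_for_random_vectors(self, rng):
        # any orientation distribution keeps S_CD within [-0.5, 1]
        v = rng.normal(size=(30, 10, 3))
        c = np.zeros((30, 10, 3))
        pos = np.empty((30, 20, 3))
        pos[:, ::2] = c
        pos[:, 1::2] = c + 0.109 * v / np.linalg.norm(v, axis=-1, keepdims=True)
        roles = ["CD_C_2", "CD_H_2"] * 10
        mols = np.repeat(np.arange(10), 2)
        traj = _minimal_traj(pos, roles, ["upper"] * 20, mol_ids=mols)
        s = mk.order_parameters(traj).s_cd[0]
        assert -0.5 - 1e-12 <= s <= 1.0 + 1e-12


class TestDiffusion:
    def test_unit_conversion_identity(self):
        assert 5.45e-6 * CM2_PER_S_PER_NM2_PER_PS == pytest.approx(5.45e-8)

    def test_msd_equals_brute_force_double_loop(self, rng):
        pos = rng.normal(size=(15, 4, 2))
        fast = _msd_time_origin_average(pos)
        for lag in range(1, 15):
            acc = [
                np.sum((pos[t + lag, i] - pos[t, i]) ** 2)
                for t in range(15 - lag)
                for i in range(pos.shape[1])
            ]
            assert fast[lag] == pytest.approx(np.mean(acc), rel=1e-12)

    def test_immobile_particles_give_zero(self):
        spec = mk.BilayerSpec(n_lipids_per_leaflet=8, n_solutes=0, n_frames=120,
                              target_D=0.0, target_scd=(0.1,), seed=0)
        traj = mk.gen_bilayer_trajectory(spec)
        assert mk.lateral_diffusion(traj).d_coeff == pytest.approx(0.0, abs=1e-20)

    def test_brownian_recovery_against_closed_form(self):
        d_true = 5.45e-8
        spec = mk.BilayerSpec(n_lipids_per_leaflet=64, n_solutes=0, n_frames=400,
                              target_D=d_true, target_scd=(0.14,), seed=11)
        traj = mk.gen_bilayer_trajectory(spec)
        # closed form MSD = 4 D dt on the true unwrapped coordinates
        curve = mk.lateral_diffusion(traj, remove_leaflet_com=False,
                                     use_unwrapped=True)
        assert curve.d_coeff == pytest.approx(d_true, rel=0.15)
        # wrapped + min-image unwrapping must agree with the retained truth
        curve_wrapped = mk.lateral_diffusion(traj, remove_leaflet_com=False)
        assert curve_wrapped.d_coeff == pytest.approx(curve.d_coeff, rel=1e-9)

    def test_too_few_frames_rejected(self, rng):
        pos = rng.normal(size=(20, 2, 3))
        traj = _minimal_traj(pos % 10.0, ["P", "P"], ["upper", "lower"])
        with pytest.raises(ValueError, match="100 frames"):
            mk.lateral_diffusion(traj)


class TestDensityProfile:
    def test_mass_conservation(self, small_traj):
        prof = mk.density_profile(small_traj, {"phosphate": "P"}, bin_width=0.1)
        from membranekit.constants import KG_PER_AMU

        area = small_traj.box[0, 0] * small_traj.box[0, 1]
        total_kg = np.sum(prof.density["phosphate"]) * prof.bin_width * area * 1e-27
        expected = small_traj.mass[small_traj.select(role="P")].sum() * KG_PER_AMU
        assert total_kg == pytest.approx(expected, rel=1e-9)

    def test_symmetrization_idempotent_on_symmetric_input(self, small_traj):
        p1 = mk.density_profile(small_traj, {"p": "P"}, symmetrize=True)
        # symmetrizing an already-symmetric profile changes nothing
        rho = p1.density["p"]
        np.testing.assert_allclose(rho, 0.5 * (rho + rho[::-1]), rtol=1e-12)

    def test_solute_overlaps_carbonyl_more_than_terminal(self, small_traj):
        prof = mk.density_profile(
            small_traj,
            {"solute": "SOLUTE", "carbonyl": "CARBONYL", "terminal": "TERMINAL_CH3"},
            bin_width=0.1, symmetrize=True,
        )

        def overlap(a, b):
            a = a / a.sum() if a.sum() else a
            b = b / b.sum() if b.sum() else b
            return np.minimum(a, b).sum()

        assert overlap(prof.density["solute"], prof.density["carbonyl"]) > overlap(
            prof.density["solute"], prof.density["terminal"]
        )

    def test_translation_invariance(self, small_traj):
        shifted = LabeledTrajectory(
            time=small_traj.time, box=small_traj.box,
            molecule_id=small_traj.molecule_id, role=small_traj.role,
            leaflet=small_traj.leaflet, mass=small_traj.mass,
            positions=small_traj.positions + np.array([0.0, 0.0, 0.7]),
        )
        p0 = mk.density_profile(small_traj, {"p": "P"}, bin_width=0.1)
        p1 = mk.density_profile(shifted, {"p": "P"}, bin_width=0.1)
        # densities are about the bilayer center, so a global z shift is invisible
        np.testing.assert_allclose(p0.density["p"], p1.density["p"], rtol=1e-9)


class TestClusters:
    def test_all_separated_gives_all_monomers(self):
        pos = np.zeros((1, 3, 3))
        pos[0] = [[0, 0, 0], [2, 0, 0], [4, 0, 0]]
        traj = _minimal_traj(pos, ["SOLUTE"] * 3, ["none"] * 3)
        rep = mk.cluster_stats(traj, cutoff=0.30)
        assert rep.percent_monomers == 100.0

    def test_single_pair_enumeration(self):
        pos = np.zeros((1, 3, 3))
        pos[0] = [[0, 0, 0], [0.2, 0, 0], [3, 3, 0]]
        traj = _minimal_traj(pos, ["SOLUTE"] * 3, ["none"] * 3)
        rep = mk.cluster_stats(traj, cutoff=0.30)
        assert sorted(rep.sizes_per_frame[0].tolist()) == [1, 2]
        assert rep.percent_monomers == pytest.approx(100 / 3)

    def test_periodic_neighbors_detected(self):
        # pair straddling the periodic boundary
        pos = np.zeros((1, 2, 3))
        pos[0] = [[0.05, 0, 0], [9.9, 0, 0]]
        traj = _minimal_traj(pos, ["SOLUTE"] * 2, ["none"] * 2, box=(10, 10, 10))
        assert mk.cluster_stats(traj, cutoff=0.30).percent_monomers == 0.0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monomer_fraction_nonincreasing_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        pos = (rng.random((2, 8, 3)) * 3.0)[..., :]
        traj = _minimal_traj(pos, ["SOLUTE"] * 8, ["none"] * 8, box=(3, 3, 3))
        pcts = [mk.cluster_stats(traj, cutoff=c).percent_monomers
                for c in (0.1, 0.3, 0.6, 1.0)]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_generator_hits_target_monomer_fraction(self):
        spec = mk.BilayerSpec(n_lipids_per_leaflet=64, n_solutes=14, n_frames=300,
                              monomer_fraction=66.6, target_scd=(0.14,), seed=5)
        traj = mk.gen_bilayer_trajectory(spec)
        rep = mk.cluster_stats(traj, cutoff=0.30)
        assert rep.percent_monomers == pytest.approx(66.6, abs=2.5)
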
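"""Generator contracts: determinism, noiseless exactness, analytic moments."""

import numpy as np
import pytest

import membranekit as mk
from membranekit.constants import kT_kj
from membranekit.presets import gaussian_barrier_profile
from membranekit.syngen import PackingError, _cluster_sizes


class TestBilayerGenerator:
    def test_same_spec_same_seed_bit_identical(self):
        spec = mk.BilayerSpec(n_lipids_per_leaflet=8, n_solutes=4, n_frames=10,
                              target_scd=(0.1,), seed=7)
        a = mk.gen_bilayer_trajectory(spec)
        b = mk.gen_bilayer_trajectory(spec)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.box, b.box)

    def test_different_seed_differs(self):
        kw = dict(n_lipids_per_leaflet=8, n_solutes=0, n_frames=10, target_scd=(0.1,))
        a = mk.gen_bilayer_trajectory(mk.BilayerSpec(seed=1, **kw))
        b = mk.gen_bilayer_trajectory(mk.BilayerSpec(seed=2, **kw))
        assert not np.array_equal(a.positions, b.positions)

    def test_zero_diffusion_freezes_lateral_motion(self):
        spec = mk.BilayerSpec(n_lipids_per_leaflet=8, n_solutes=0, n_frames=20,
                              target_D=0.0, target_scd=(0.1,), seed=0)
        traj = mk.gen_bilayer_trajectory(spec)
        p = traj.select(role="P")
        xy = traj.positions_unwrapped[:, p, :2]
        assert np.all(xy == xy[0])

    def test_zero_z_noise_gives_exact_thickness(self):
        spec = mk.BilayerSpec(n_lipids_per_leaflet=8, n_solutes=0, n_frames=5,
                              target_thickness=3.5, z_noise_sd=0.0,
                              target_scd=(0.1,), seed=0)
        traj = mk.gen_bilayer_trajectory(spec)
        assert mk.membrane_thickness(traj).mean == pytest.approx(3.5, abs=1e-12)

    def test_box_area_matches_target_apl(self):
        spec = mk.BilayerSpec(n_lipids_per_leaflet=50, n_solutes=0, n_frames=2,
                              target_apl=0.7, target_scd=(0.1,), seed=0)
        traj = mk.gen_bilayer_trajectory(spec)
        assert traj.box[0, 0] * traj.box[0, 1] == pytest.approx(50 * 0.7)

    def test_unsatisfiable_packing_raises(self):
        # tiny bilayer, far too many solutes for the required separations
        spec = mk.BilayerSpec(n_lipids_per_leaflet=2, n_solutes=40, n_frames=1,
                              monomer_fraction=100.0, target_scd=(0.1,), seed=0)
        with pytest.raises(PackingError):
            mk.gen_bilayer_trajectory(spec)

    def test_cluster_size_expectation_matches_target(self, rng):
        n, target = 14, 66.6
        fracs = [
            np.sum(np.array(_cluster_sizes(n, target, rng)) == 1) / n
            for _ in range(4000)
        ]
        assert 100 * np.mean(fracs) == pytest.approx(target, abs=0.6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            mk.BilayerSpec(n_lipids_per_leaflet=0)
        with pytest.raises(ValueError):
            mk.BilayerSpec(monomer_fraction=130.0)
        with pytest.raises(ValueError):
            mk.BilayerSpec(dt=-1.0)


class TestPartitionGenerator:
    def test_half_saturation_identity(self):
        data = mk.gen_partition_data(0.3, 1.2, [1.2], noise_sd=0.0)
        assert data.r_mem[0] == pytest.approx(0.15)

    def test_zero_x_gives_zero(self):
        data = mk.gen_partition_data(0.3, 1.2, [0.0], noise_sd=0.0)
        assert data.r_mem[0] == 0.0

    def test_hyperbolic_shape_with_reference_parameters(self):
        # saturating, monotone, approaching R_sat = 0.30 from below
        x = np.linspace(0.25, 4.0, 12)
        data = mk.gen_partition_data(0.30, 1.2, x, noise_sd=0.0)
        assert np.all(np.diff(data.r_mem) > 0)
        assert data.r_mem[-1] < 0.30
        assert data.r_mem[-1] == pytest.approx(0.30 * 4.0 / 5.2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            mk.gen_partition_data(0.3, 1.2, [1.0], noise_sd=-0.1)

    def test_noise_truncated_at_zero(self):
        data = mk.gen_partition_data(0.01, 1.2, [0.01] * 50, noise_sd=0.5, seed=3)
        assert np.all(data.r_mem >= 0)


class TestLeakageGenerator:
    def test_zero_time_zero_leakage(self):
        p = mk.LeakageSimParams(plateau_percent=60, rate_constant=0.01, noise_sd=0)
        trace = mk.gen_leakage_trace(p, np.linspace(0, 100, 11))
        assert trace.percent()[0] == pytest.approx(0.0)

    def test_long_time_reaches_plateau(self):
        p = mk.LeakageSimParams(plateau_percent=60, rate_constant=0.05, noise_sd=0)
        trace = mk.gen_leakage_trace(p, np.linspace(0, 1000, 101))
        assert trace.percent()[-1] == pytest.approx(60.0, abs=1e-6)

    def test_composition_modifier_orders_traces(self):
        # rate-enhanced > baseline > protected at every t > 0
        t = np.linspace(0, 600, 61)
        traces = {
            m: mk.gen_leakage_trace(
                mk.LeakageSimParams(plateau_percent=60, rate_constant=0.01,
                                    composition_modifier=m, noise_sd=0), t)
            for m in (2.0, 1.0, 0.5)
        }
        hi, mid, lo = (traces[m].percent()[1:] for m in (2.0, 1.0, 0.5))
        assert np.all(hi > mid) and np.all(mid > lo)


class TestUmbrellaGenerator:
    def test_flat_profile_gives_analytic_gaussian_moments(self):
        # p_i is exactly Gaussian: mean z_i, variance kT/k
        k, T = 1000.0, 298.0
        flat = mk.FreeEnergyProfile(z=np.linspace(-1, 3, 401), g=np.zeros(401))
        w = mk.gen_umbrella_samples(flat, [1.0], k_spring=k, n_per_window=200_000,
                                    temperature=T, seed=9)
        s = w.samples[0]
        var_expected = kT_kj(T) / k
        assert s.mean() == pytest.approx(1.0, abs=3 * np.sqrt(var_expected / len(s)))
        assert s.var() == pytest.approx(var_expected, rel=0.02)

    def test_stiff_spring_collapses_onto_center(self):
        flat = mk.FreeEnergyProfile(z=np.linspace(-1, 3, 401), g=np.zeros(401))
        w = mk.gen_umbrella_samples(flat, [1.0], k_spring=1e7, n_per_window=100, seed=0)
        assert np.allclose(w.samples[0], 1.0, atol=0.01)

    def test_same_seed_identical_samples(self):
        prof = gaussian_barrier_profile(3.0)
        w1 = mk.gen_umbrella_samples(prof, [0.0, 0.5], n_per_window=50, seed=5)
        w2 = mk.gen_umbrella_samples(prof, [0.0, 0.5], n_per_window=50, seed=5)
        for a, b in zip(w1.samples, w2.samples):
            assert np.array_equal(a, b)

    def test_profile_must_cover_windows(self):
        narrow = mk.FreeEnergyProfile(z=np.linspace(0, 1, 101), g=np.zeros(101))
        with pytest.raises(ValueError, match="cover"):
            mk.gen_umbrella_samples(narrow, [0.0, 1.0], n_per_window=10, seed=0)


class TestScatteringGenerator:
    def test_three_orders_peak_positions(self):
        # s_n = n/d arithmetic at d = 59.6 A
        c = mk.gen_scattering_curve(59.6, 3, noise_sd=0.0, background=0.0, seed=0)
        for n, expected in [(1, 0.016779), (2, 0.033557), (3, 0.050336)]:
            i = np.argmin(np.abs(c.s - expected))
            window = c.intensity[max(i - 5, 0): i + 6]
            assert c.intensity[i] == pytest.approx(window.max(), rel=1e-3)

    def test_noiseless_maxima_at_reflections(self):
        c = mk.gen_scattering_curve(59.6, 1, noise_sd=0.0, background=0.0, seed=0)
        s_peak = c.s[np.argmax(c.intensity)]
        ds = c.s[1] - c.s[0]
        assert abs(s_peak - 1 / 59.6) <= ds

    def test_calibration_reference_curve(self):
        # silver stearate single-order reference at d = 48.8 A
        c = mk.gen_scattering_curve(48.8, 1, noise_sd=0.0, background=0.0, seed=0)
        s_peak = c.s[np.argmax(c.intensity)]
        assert s_peak == pytest.approx(1 / 48.8, abs=c.s[1] - c.s[0])

    def test_out_of_range_order_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            mk.gen_scattering_curve(59.6, 5, noise_sd=0.0, seed=0)
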
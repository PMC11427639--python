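"""ACRC, profiles, cAVH, logistic recovery curves and region-based PVC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import fftconvolve

import holoquant as hq
from holoquant.phantom_geometry import JASZCZAK_SPHERE_DIAMETERS_MM


class TestACRC:
    def test_exact_truth_gives_unity(self, jz_spec, sim_grid, jz_truth0, metrics_vois):
        q = hq.QuantifiedVolume(sim_grid, jz_truth0.values, "exact")
        whole = hq.voxelize_cylinder(216, 186, grid=sim_grid)
        assert hq.acrc(q, whole, jz_truth0.mean_in(whole)) == pytest.approx(1.0)

    def test_matches_independent_convolution_oracle(self):
        """Blur-only ACRC of a hot sphere equals an explicit-kernel oracle."""
        grid = hq.VoxelGrid.centered(160, 2.0)
        sphere = hq.voxelize_sphere(60, (0, 0, 0), grid)
        body = hq.voxelize_cylinder(150, 150, grid=grid)
        truth_vals = np.where(sphere.mask, 4.10, np.where(body.mask, 0.41, 0.0))
        truth = hq.ActivityVolume(grid, truth_vals)
        blurred = hq.apply_psf(truth, 15.0)
        q = hq.QuantifiedVolume(grid, blurred.values, "blur")
        measured = hq.acrc(q, sphere, 4.10)

        sigma_vox = 15.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
        radius = int(4.0 * sigma_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma_vox) ** 2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        oracle_vol = fftconvolve(truth_vals, kernel, mode="same")
        oracle = oracle_vol[sphere.mask].mean() / 4.10
        assert measured == pytest.approx(oracle, abs=1e-3)

    def test_monotone_in_sphere_diameter_under_blur(self, noiseless_acrcs):
        vals = [noiseless_acrcs[f"sphere_{i}"] for i in range(1, 7)]
        assert np.all(np.diff(vals) > 0)

    def test_background_overestimated_when_spheres_underrecovered(self, noiseless_acrcs):
        """Self-calibration pushes sphere spill-out into the background VOI."""
        assert noiseless_acrcs["sphere_6"] < 1.0
        assert noiseless_acrcs["background"] > 1.0

    def test_sum_rule_restates_total_conservation(
        self, jz_spec, sim_grid, noiseless_selfcal, jz_truth0
    ):
        """Sum of ACRC * AC_true * V_VOI over the VOI partition = injected activity."""
        vois = hq.build_jaszczak_vois(jz_spec, sim_grid)
        total = 0.0
        for i in range(1, 7):
            v = vois[f"sphere_{i}"]
            total += hq.acrc(noiseless_selfcal, v, 4.10) * 4.10 * v.volume_ml
        bg = vois["background"]
        total += hq.acrc(noiseless_selfcal, bg, 0.41) * 0.41 * bg.volume_ml
        assert total == pytest.approx(jz_truth0.total, rel=1e-9)

    def test_empty_voi_and_bad_truth_rejected(self, sim_grid):
        q = hq.QuantifiedVolume(sim_grid, np.zeros(sim_grid.shape), "x")
        empty = hq.VOIMask(sim_grid, np.zeros(sim_grid.shape, bool), "empty")
        with pytest.raises(ValueError, match="empty"):
            hq.acrc(q, empty, 1.0)
        full = hq.VOIMask(sim_grid, np.ones(sim_grid.shape, bool), "all")
        with pytest.raises(ValueError):
            hq.acrc(q, full, 0.0)


class TestProfiles:
    @staticmethod
    def _uniform_cylinder_q(noise_rng=None):
        spec = hq.cylinder_phantom(concentration=0.5, diameter_mm=160, height_mm=160)
        grid = hq.VoxelGrid.centered(200, 4.0)
        vals = hq.ground_truth_map(spec, grid, 0.0).values
        if noise_rng is not None:
            vals = vals * noise_rng.normal(1.0, 0.2, vals.shape)
        return spec, hq.QuantifiedVolume(grid, vals, "t")

    def test_uniform_unblurred_profiles_are_flat_at_truth(self):
        spec, q = self._uniform_cylinder_q()
        profiles = hq.activity_profiles(
            q, spec, rows=[(0.0, 0.0)], radii=[30.0, 70.0], margin_mm=30.0
        )
        for p in profiles:
            lo, hi = p.percent_of_true_range(0.5)
            assert lo == pytest.approx(100.0) and hi == pytest.approx(100.0)

    def test_radius_averaging_reduces_span_vs_single_row(self):
        spec, q = self._uniform_cylinder_q(np.random.default_rng(5))
        row, ring = hq.activity_profiles(
            q, spec, rows=[(0.0, 0.0)], radii=[70.0], margin_mm=30.0
        )
        assert np.ptp(row.values) > np.ptp(ring.values)

    def test_simulated_filtered_phantom_radius70_within_10_percent(self):
        """Large-radius average of a noisy filtered scan stays near truth."""
        spec = hq.cylinder_phantom()
        grid = hq.VoxelGrid.centered(260, 4.8)
        truth = hq.ground_truth_map(spec, grid, 0.0)
        counts = hq.simulate_acquisition(truth, hq.AcquisitionSpec(seed=11))
        voi = hq.voxelize_cylinder(140, 130, grid=grid, label="cal")
        cf = hq.compute_cf(counts, voi, 0.049 * voi.volume_ml)
        q = hq.quantify_with_cf(counts, cf, 0.0)
        (p,) = hq.activity_profiles(q, spec, radii=[70.0], margin_mm=30.0)
        lo, hi = p.percent_of_true_range(0.049)
        assert 90.0 < lo and hi < 110.0

    def test_radius_exceeding_phantom_rejected(self):
        spec, q = self._uniform_cylinder_q()
        with pytest.raises(ValueError, match="exceeds"):
            hq.activity_profiles(q, spec, radii=[90.0])

    def test_row_outside_phantom_rejected(self):
        spec, q = self._uniform_cylinder_q()
        with pytest.raises(ValueError, match="outside"):
            hq.activity_profiles(q, spec, rows=[(90.0, 0.0)])


class TestCAVH:
    def test_homogeneous_volume_is_step_function(self, sim_grid):
        vals = np.zeros(sim_grid.shape)
        body = hq.voxelize_cylinder(100, 100, grid=sim_grid)
        vals[body.mask] = 2.0
        q = hq.QuantifiedVolume(sim_grid, vals, "t")
        curve = hq.cavh(q, body, thresholds=np.array([0.0, 1.0, 2.0, 2.5]))
        assert list(curve.fractions) == [1.0, 1.0, 1.0, 0.0]

    def test_half_filled_voi_fraction_half(self, sim_grid):
        body = hq.voxelize_cylinder(100, 100, grid=sim_grid)
        vals = np.zeros(sim_grid.shape)
        idx = np.argwhere(body.mask)
        half = idx[: len(idx) // 2]
        vals[tuple(half.T)] = 3.0
        q = hq.QuantifiedVolume(sim_grid, vals, "t")
        curve = hq.cavh(q, body, thresholds=np.array([0.0, 1.5, 3.0]))
        assert curve.fractions[0] == 1.0
        assert curve.fractions[1] == pytest.approx(0.5, abs=0.01)
        assert curve.fractions[2] == pytest.approx(0.5, abs=0.01)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_equals_empirical_survival_function(self, data):
        vals = data.draw(
            st.lists(st.floats(0, 10, allow_nan=False), min_size=8, max_size=64)
        )
        thr = sorted(
            data.draw(st.lists(st.floats(0, 12, allow_nan=False), min_size=1, max_size=10))
        )
        n = len(vals)
        grid = hq.VoxelGrid((n, 1, 1), (1, 1, 1))
        arr = np.asarray(vals).reshape(n, 1, 1)
        q = hq.QuantifiedVolume(grid, arr, "t")
        voi = hq.VOIMask(grid, np.ones((n, 1, 1), bool), "all")
        curve = hq.cavh(q, voi, thresholds=np.asarray(thr))
        expected = [np.mean(np.asarray(vals) >= t) for t in thr]
        assert np.allclose(curve.fractions, expected)
        assert np.all(np.diff(curve.fractions) <= 0)


class TestRecoveryCurveFit:
    def test_exact_parameter_recovery_on_noiseless_logistic(self):
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        y = hq.logistic_recovery(d, 0.9, 20.0, 3.0)
        fit = hq.fit_recovery_curve(d, y)
        assert fit.a == pytest.approx(0.9, abs=1e-6)
        assert fit.b == pytest.approx(20.0, abs=1e-5)
        assert fit.c == pytest.approx(3.0, abs=1e-5)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_half_maximum_property(self):
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        fit = hq.fit_recovery_curve(d, hq.logistic_recovery(d, 0.9, 20.0, 3.0))
        assert fit.predict(fit.b) == pytest.approx(fit.a / 2)

    def test_unbiased_over_noisy_replicates(self):
        """Mean fitted asymptote over 200 sd=0.02 replicates within 2% of truth."""
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        y0 = hq.logistic_recovery(d, 0.9, 20.0, 3.0)
        rng = np.random.default_rng(123)
        a_hat = [
            hq.fit_recovery_curve(d, y0 + rng.normal(0, 0.02, 6), n_restarts=2, seed=k).a
            for k in range(200)
        ]
        assert abs(np.mean(a_hat) - 0.9) < 0.02 * 0.9

    def test_noiseless_jaszczak_acrcs_fit_well(self, noiseless_acrcs):
        vals = [noiseless_acrcs[f"sphere_{i}"] for i in range(1, 7)]
        fit = hq.fit_recovery_curve(JASZCZAK_SPHERE_DIAMETERS_MM, vals)
        assert fit.r2 > 0.99

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 4"):
            hq.fit_recovery_curve([10, 20, 30], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="distinct"):
            hq.fit_recovery_curve([10, 10, 20, 30], [0.1, 0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="requires"):
            hq.fit_recovery_curve([10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4], weighted=True)

    def test_weighted_fit_uses_sds(self):
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        y = hq.logistic_recovery(d, 0.9, 20.0, 3.0)
        fit = hq.fit_recovery_curve(d, y, acrc_sds=np.full(6, 0.01), weighted=True)
        assert fit.a == pytest.approx(0.9, abs=1e-5)


class TestPVC:
    def test_simple_ratio(self):
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        fit = hq.fit_recovery_curve(d, hq.logistic_recovery(d, 1.0, 20.0, 3.0))
        d_half = fit.b  # recovery is exactly 0.5 there
        assert hq.apply_pvc(1.0, d_half, fit) == pytest.approx(2.0, rel=1e-6)

    def test_large_diameter_correction_tends_to_inverse_asymptote(self):
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        fit = hq.fit_recovery_curve(d, hq.logistic_recovery(d, 0.8, 20.0, 3.0))
        assert hq.apply_pvc(1.0, 1e6, fit) == pytest.approx(1 / 0.8, rel=1e-4)

    def test_roundtrip_on_blurred_sphere_within_2_percent(self, noiseless_acrcs):
        """Correcting the measured sphere-6 mean with a same-family fit."""
        vals = [noiseless_acrcs[f"sphere_{i}"] for i in range(1, 7)]
        fit = hq.fit_recovery_curve(JASZCZAK_SPHERE_DIAMETERS_MM, vals)
        measured = noiseless_acrcs["sphere_6"] * 4.10
        corrected = hq.apply_pvc(measured, 60.0, fit)
        assert corrected == pytest.approx(4.10, rel=0.02)

    def test_floor_refuses_unstable_correction(self):
        d = np.array(JASZCZAK_SPHERE_DIAMETERS_MM)
        fit = hq.fit_recovery_curve(d, hq.logistic_recovery(d, 0.9, 20.0, 3.0))
        with pytest.raises(ValueError, match="floor"):
            hq.apply_pvc(1.0, 1.0, fit)
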
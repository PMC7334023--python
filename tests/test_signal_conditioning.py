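import numpy as np
import pytest

from strideloop import signal_conditioning as sc
from strideloop.recordings_io import ValidationError


class TestCalibration:
    def test_exact_linear(self):
        v = np.array([0.0, 1.0, 2.0, 3.0])
        cal = sc.calibrate_force(v, 2 * v)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.acceptable()

    def test_below_threshold_flagged(self, rng):
        # noisy enough that R^2 ~ 0.9: flagged per the >0.97 acceptance rule
        v = np.linspace(0, 1, 40)
        loads = 5 * v + rng.normal(0, 1.2, v.size)
        with pytest.warns(sc.CalibrationWarning):
            cal = sc.calibrate_force(v, loads)
        assert not cal.acceptable(0.97)
        with pytest.raises(ValidationError):
            sc.calibrate_force(v, loads, strict=True)

    def test_ols_recovery_within_2pc(self, rng):
        v = np.linspace(0.1, 2.0, 50)
        loads = 3.7 * v + 0.5 + rng.normal(0, 0.01 * 3.7 * v.mean(), v.size)
        cal = sc.calibrate_force(v, loads)
        assert cal.slope == pytest.approx(3.7, rel=0.02)

    def test_linearity_in_input_scale(self):
        v = np.array([0.1, 0.5, 1.0, 1.5])
        loads = 4.0 * v + 1.0
        cal = sc.calibrate_force(v, loads)
        x = np.array([0.2, 0.7, 1.3])
        a = 2.5
        # calibrating a*volts scales the recovered slope by 1/a, so the
        # applied force for a*x matches the original prediction
        cal2 = sc.calibrate_force(a * v, loads)
        np.testing.assert_allclose(cal2.apply(a * x), cal.apply(x))

    def test_degenerate_input(self):
        with pytest.raises(ValidationError):
            sc.calibrate_force([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


class TestSmoothing:
    def test_cubic_polynomial_reproduced(self):
        x = np.linspace(0, 1, 500)
        y = 1 + 2 * x - 3 * x ** 2 + 0.5 * x ** 3
        # a tight residual bound reproduces a noise-free cubic exactly
        out = sc.smooth_length(y, tolerance=0.0)
        np.testing.assert_allclose(out, y, atol=1e-9)
        # the default bound spends at most its residual budget
        out = sc.smooth_length(y, tolerance=0.1)
        assert np.sum((y - out) ** 2) <= 0.1 * 1.0001

    def test_zero_tolerance_interpolates(self, rng):
        y = rng.normal(0, 1, 200)
        out = sc.smooth_length(y, tolerance=0.0)
        np.testing.assert_array_equal(out, y)

    def test_rss_bound_respected(self, rng):
        t = np.arange(2000) / 1000
        y = 17 + np.sin(2 * np.pi * 3 * t) + rng.normal(0, 0.05, t.size)
        for tol in (0.5, 2.0):
            out = sc.smooth_length(y, tolerance=tol)
            assert np.sum((y - out) ** 2) <= tol * 1.0001

    def test_larger_tolerance_never_rougher(self, rng):
        t = np.arange(1500) / 1000
        y = 17 + np.sin(2 * np.pi * 3 * t) + rng.normal(0, 0.05, t.size)
        rough = [sc.roughness(sc.smooth_length(y, tolerance=tol), 1e-3)
                 for tol in (0.01, 0.5, 3.0)]
        assert rough[0] >= rough[1] >= rough[2]

    def test_all_nan_rejected(self):
        with pytest.raises(ValidationError):
            sc.smooth_length(np.full(100, np.nan))


class TestRepair:
    def test_no_artifacts_identity(self, rng):
        t = np.arange(1000) / 1000
        y = 17 + np.sin(2 * np.pi * 2 * t) + rng.normal(0, 0.01, t.size)
        out, bad = sc.repair_dropouts(y)
        np.testing.assert_array_equal(out, y)
        assert not bad.any()

    def test_short_dropout_filled_within_1pc(self):
        t = np.arange(2000) / 1000
        truth = 17 + np.sin(2 * np.pi * 2 * t)
        y = truth.copy()
        y[800:805] = np.nan
        out, bad = sc.repair_dropouts(y, gap_limit=100)
        assert not bad.any()
        np.testing.assert_allclose(out[800:805], truth[800:805], rtol=0.01)

    def test_long_gap_flagged_not_filled(self):
        t = np.arange(5000) / 1000
        y = 17 + np.sin(2 * np.pi * 2 * t)
        y[1000:2500] = np.nan
        out, bad = sc.repair_dropouts(y, gap_limit=100)
        assert bad[1000:2500].all()
        assert not bad[:1000].any() and not bad[2500:].any()

    def test_level_shift_removed(self):
        # the shorter (artifact) segment is offset back onto the longer one
        t = np.arange(3000) / 1000
        truth = 17 + np.sin(2 * np.pi * 2 * t)
        y = truth.copy()
        y[2000:] += 5.0  # level-shift artifact on the shorter tail
        out, _ = sc.repair_dropouts(y)
        assert np.abs(out - truth).max() < 0.05

    def test_level_shift_with_noise(self, rng):
        t = np.arange(3000) / 1000
        sigma = 0.02
        noise = rng.normal(0, sigma, t.size)
        truth = 17 + np.sin(2 * np.pi * 2 * t) + noise
        y = truth.copy()
        y[2400:] -= 4.0
        out, _ = sc.repair_dropouts(y)
        assert np.abs(out - truth).max() < 8 * sigma

    def test_all_nan_rejected(self):
        with pytest.raises(ValidationError):
            sc.repair_dropouts(np.full(10, np.nan))


class TestFractionalLength:
    def test_constant_signal(self):
        y = np.full(100, 17.0)
        L, L_o = sc.fractional_length(y, reference_mask=np.ones(100, bool))
        assert L_o == pytest.approx(17.0)
        np.testing.assert_allclose(L, 1.0)

    def test_reference_mean_is_one(self, rng):
        y = 18 + rng.normal(0, 0.5, 500)
        mask = np.zeros(500, bool)
        mask[100:400] = True
        L, L_o = sc.fractional_length(y, reference_mask=mask)
        assert np.mean(L[mask]) == pytest.approx(1.0, abs=1e-9)

    def test_missing_reference_instructs_caller(self):
        with pytest.raises(ValidationError, match="L_o"):
            sc.fractional_length(np.ones(10))

    def test_known_L_o_recovered_from_generator(self, noise_free_run):
        merged, cycles, gt = noise_free_run
        for bird, expected in gt.L_o_mm.items():
            got = {c.L_o_mm for c in cycles if c.bird_id == bird}.pop()
            assert got == pytest.approx(expected, rel=1e-3)


class TestVelocity:
    def test_analytic_sine_derivative(self):
        fs = 10000.0
        t = np.arange(int(fs)) / fs
        L = np.sin(2 * np.pi * t)
        V = sc.differentiate(L, 1 / fs)
        np.testing.assert_allclose(V, 2 * np.pi * np.cos(2 * np.pi * t), atol=1e-4)

    def test_constant_length_zero_velocity(self):
        V = sc.differentiate(np.full(100, 1.0), 1e-3)
        np.testing.assert_array_equal(V, 0.0)

    def test_shortening_is_negative(self):
        L = np.linspace(1.1, 0.9, 50)
        assert (sc.differentiate(L, 1e-3) < 0).all()

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            sc.differentiate(np.array([1.0, 2.0]), 1e-3)

    def test_differentiate_integrate_identity(self):
        from scipy.integrate import cumulative_trapezoid
        fs = 5000.0
        t = np.arange(int(fs)) / fs
        L = 1 + 0.1 * np.sin(2 * np.pi * 2.5 * t)
        V = sc.differentiate(L, 1 / fs)
        L_back = L[0] + cumulative_trapezoid(V, dx=1 / fs, initial=0.0)
        rms = np.sqrt(np.mean((L_back - L) ** 2)) / np.ptp(L)
        assert rms < 1e-3


class TestEMGConditioning:
    fs = 10000.0

    def test_dc_offset_removed(self):
        x = np.full(int(self.fs), 0.8)
        out = sc.condition_emg(x, self.fs)
        assert np.mean(out) < 0.01 * 0.8

    def test_150hz_tone_passes(self):
        t = np.arange(int(self.fs)) / self.fs
        x = np.sin(2 * np.pi * 150 * t)
        y = sc.condition_emg(x, self.fs, rectify=False)
        mid = slice(2000, 8000)
        gain = np.std(y[mid]) / np.std(x[mid])
        assert gain >= 0.99

    def test_5hz_drift_attenuated_20db(self):
        t = np.arange(int(2 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 5 * t)
        y = sc.condition_emg(x, self.fs, rectify=False)
        mid = slice(5000, 15000)
        atten_db = 20 * np.log10(np.std(x[mid]) / max(np.std(y[mid]), 1e-300))
        assert atten_db >= 20

    def test_inverted_band_rejected(self):
        with pytest.raises(ValidationError):
            sc.condition_emg(np.zeros(100), self.fs, band=(500, 100))

    def test_sample_rate_too_low(self):
        with pytest.raises(ValidationError):
            sc.condition_emg(np.zeros(100), 1500.0, band=(10, 1000))
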
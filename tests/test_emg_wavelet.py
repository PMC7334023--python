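import numpy as np
import pytest
from scipy import signal as sps

from strideloop import emg_wavelet as ew
from strideloop.recordings_io import ValidationError


@pytest.fixture(scope="module")
def bank():
    return ew.FilterBank.default()


class TestFilterbank:
    def test_default_band_span(self, bank):
        cfs = bank.center_frequencies
        assert len(cfs) == 11
        assert 6 < cfs[0] < 8 and 380 < cfs[-1] < 410
        assert (np.diff(cfs) > 0).all()

    def test_zero_signal_zero_intensity(self, bank):
        spec = ew.wavelet_intensity(np.zeros(4096), 2000.0, bank)
        assert np.all(spec.intensity == 0)
        assert np.all(spec.total_intensity == 0)

    def test_tone_maximizes_matching_band(self, bank):
        fs = 2000.0
        t = np.arange(8192) / fs
        for f0 in (37.7, 128.5, 218.1):
            x = np.sin(2 * np.pi * f0 * t)
            spec = ew.wavelet_intensity(x, fs, bank)
            band_power = spec.intensity[:, 2000:6000].mean(axis=1)
            best = np.argmax(band_power)
            nearest = np.argmin(np.abs(bank.center_frequencies - f0))
            assert best == nearest

    def test_amplitude_scaling_quadratic(self, bank, rng):
        x = rng.normal(0, 1, 4096)
        s1 = ew.wavelet_intensity(x, 2000.0, bank)
        s3 = ew.wavelet_intensity(3 * x, 2000.0, bank)
        np.testing.assert_allclose(s3.intensity, 9 * s1.intensity, rtol=1e-9)

    def test_band_above_nyquist_rejected(self, bank):
        with pytest.raises(ValidationError):
            ew.wavelet_intensity(np.zeros(100), 700.0, bank)

    def test_intensity_nonnegative_and_totals_consistent(self, bank, rng):
        x = rng.normal(0, 1, 2048)
        spec = ew.wavelet_intensity(x, 2000.0, bank)
        assert (spec.intensity >= 0).all()
        np.testing.assert_allclose(spec.total_intensity, spec.intensity.sum(0))

    def test_parseval_coverage_inband_noise(self, bank, rng):
        """E_tot within 20% of the integral of the squared band-passed EMG."""
        fs = 2000.0
        sos = sps.butter(4, [30, 350], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.normal(0, 1, 2 ** 14))
        spec = ew.wavelet_intensity(x, fs, bank)
        e_tot, _ = ew.emg_totals(spec, (0, x.size))
        ref = np.trapezoid(x ** 2, dx=1 / fs)
        assert e_tot == pytest.approx(ref, rel=0.20)

    def test_morlet_alternative_same_contract(self, bank, rng):
        x = rng.normal(0, 1, 2048)
        spec = ew.wavelet_intensity(x, 2000.0, bank, method="morlet")
        assert spec.intensity.shape == (11, 2048)
        assert (spec.intensity >= 0).all()


class TestTotals:
    def test_silence(self, bank):
        spec = ew.wavelet_intensity(np.zeros(1000), 2000.0, bank)
        e_tot, e_freq = ew.emg_totals(spec, (0, 1000))
        assert e_tot == 0.0 and e_freq is None

    def test_two_equal_bands_mean_frequency(self):
        cfs = np.array([100.0, 200.0])
        intensity = np.ones((2, 500))
        spec = ew.IntensitySpectrum(cfs, intensity, 1000.0)
        _, e_freq = ew.emg_totals(spec, (0, 500))
        assert e_freq == pytest.approx(150.0)

    def test_bandlimited_noise_mean_frequency(self, bank, rng):
        """Noise centered at 150 Hz: E_freq ~ 150 +- 10 Hz across seeded draws."""
        fs = 2000.0
        freqs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            sos = sps.butter(6, [130, 170], btype="bandpass", fs=fs, output="sos")
            x = sps.sosfiltfilt(sos, r.normal(0, 1, 2 ** 13))
            spec = ew.wavelet_intensity(x, fs, bank)
            _, e_freq = ew.emg_totals(spec, (0, x.size))
            freqs.append(e_freq)
        assert np.mean(freqs) == pytest.approx(150.0, abs=10.0)

    def test_window_outside_span(self, bank):
        spec = ew.wavelet_intensity(np.zeros(100), 2000.0, bank)
        with pytest.raises(ValidationError):
            ew.emg_totals(spec, (0, 200))


class TestBurst:
    def test_rectangular_burst_duration(self):
        x = np.zeros(200)
        x[40:100] = 1.0  # 30% of the cycle, zero baseline
        onset, offset, e_dur = ew.detect_burst(x)
        assert e_dur == pytest.approx(0.30, abs=0.005)
        assert onset == pytest.approx(0.20, abs=0.005)

    def test_flat_intensity_no_burst(self):
        onset, offset, e_dur = ew.detect_burst(np.full(200, 0.7))
        assert onset is None and e_dur == 0.0

    def test_zero_intensity_no_burst(self):
        onset, offset, e_dur = ew.detect_burst(np.zeros(200))
        assert onset is None and e_dur == 0.0

    def test_onset_recovery_at_snr10(self, rng):
        """Known burst onset recovered within 1% of cycle at SNR 10."""
        errs = []
        for seed in range(25):
            r = np.random.default_rng(seed)
            x = np.abs(r.normal(0, 0.1, 200))      # baseline, amplitude SNR 10
            x[50:120] += 1.0
            onset, _, _ = ew.detect_burst(x)
            errs.append(onset - 50 / 200)
        assert np.max(np.abs(errs)) <= 0.01

    def test_wrapped_burst(self):
        x = np.zeros(200)
        x[180:] = 1.0
        x[:40] = 1.0  # burst spans the cycle boundary
        # quiet window moved away from the wrapped burst
        onset, offset, e_dur = ew.detect_burst(x, baseline_window=(0.45, 0.70))
        assert e_dur == pytest.approx(0.30, abs=0.01)
        assert onset == pytest.approx(0.90, abs=0.01)

    def test_time_shift_equivariance(self, bank, rng):
        """Shifting the EMG shifts the onset; E_tot and E_freq are unchanged."""
        fs, n = 2000.0, 4000
        t = np.arange(n) / fs
        env = np.zeros(n)
        env[1000:2200] = 1.0
        sos = sps.butter(4, [80, 250], btype="bandpass", fs=fs, output="sos")
        x = env * sps.sosfiltfilt(sos, rng.normal(0, 1, n))
        shift = 300
        x_shifted = np.roll(x, shift)
        res = {}
        for name, sig in [("base", x), ("shift", x_shifted)]:
            spec = ew.wavelet_intensity(sig, fs, bank)
            e_tot, e_freq = ew.emg_totals(spec, (0, n))
            intensity = spec.total_intensity[::n // 200][:200]
            onset, _, _ = ew.detect_burst(intensity)
            res[name] = (e_tot, e_freq, onset)
        assert res["shift"][0] == pytest.approx(res["base"][0], rel=0.02)
        assert res["shift"][1] == pytest.approx(res["base"][1], abs=5.0)
        d_on = (res["shift"][2] - res["base"][2]) % 1.0
        assert d_on == pytest.approx(shift / n, abs=0.01)


class TestPhase:
    def test_onset_at_peak_is_zero(self):
        assert ew.compute_phase(0.26, 0.26) == 0.0

    def test_earlier_onset_negative(self):
        assert ew.compute_phase(0.20, 0.26) == pytest.approx(-0.06)

    def test_wrap_across_cycle_boundary(self):
        assert ew.compute_phase(0.98, 0.02) == pytest.approx(-0.04)
        assert ew.compute_phase(0.02, 0.98) == pytest.approx(0.04)

    def test_missing_onset_propagates(self):
        assert ew.compute_phase(None, 0.2) is None

    def test_swing_peak_parabolic_refinement(self):
        phase = np.arange(200) / 200
        L = 1 + 0.1 * np.cos(2 * np.pi * (phase - 0.203))
        got = ew.swing_peak_phase(L, phase, contact_phase=0.5)
        assert got == pytest.approx(0.203, abs=1e-3)
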
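import numpy as np
import pytest

from pcspectra import Recording, Spectrum, band_energy, compute_psd, smooth_spectrum


def direct_welch_oracle(x, fs, window_fraction=1 / 3, pad_factor=2, overlap=0.5):
    """Independent PSD oracle: hand-rolled windowed, zero-padded, averaged DFT."""
    x = x - x.mean()
    n = x.size
    w = int(round(window_fraction * n))
    nfft = pad_factor * w
    step = w - int(round(overlap * w))
    win = np.hamming(w + 1)[:-1]  # periodic (DFT-even) Hamming
    norm = fs * np.sum(win**2)
    psds = []
    for start in range(0, n - w + 1, step):
        seg = x[start : start + w]
        seg = (seg - seg.mean()) * win
        spec = np.fft.rfft(seg, nfft)
        p = (np.abs(spec) ** 2) / norm
        p[1:-1] *= 2.0  # one-sided
        psds.append(p)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, np.mean(psds, axis=0)


class TestComputePsd:
    def test_pure_tone_is_localised_to_its_bin(self, sine_recording):
        spec = compute_psd(sine_recording)
        peak_freq = spec.freqs[np.argmax(spec.power)]
        assert abs(peak_freq - 10.0) <= spec.df

    def test_constant_signal_gives_zero_spectrum(self):
        rec = Recording(samples=np.full(3000, 5.0), fs=100.0)
        spec = compute_psd(rec)
        assert np.allclose(spec.power, 0.0)

    def test_parseval_white_noise(self, noise_recording):
        """Integrated raw one-sided density equals the sample variance (1 %)."""
        spec = compute_psd(noise_recording)
        total = np.trapezoid(spec.power, spec.freqs)
        var = noise_recording.samples.var()
        assert total == pytest.approx(var, rel=0.01)

    def test_matches_direct_dft_oracle(self, noise_recording):
        spec = compute_psd(noise_recording)
        freqs, power = direct_welch_oracle(noise_recording.samples, noise_recording.fs)
        np.testing.assert_allclose(spec.freqs, freqs)
        np.testing.assert_allclose(spec.power, power, rtol=1e-8, atol=1e-12)

    def test_grid_metadata(self, sine_recording):
        spec = compute_psd(sine_recording)
        assert spec.window_samples == 20_000
        assert spec.fft_samples == 40_000
        assert spec.df == pytest.approx(1000.0 / 40_000)
        assert spec.power[0] == pytest.approx(0.0, abs=1e-10)

    def test_too_short_recording_rejected(self):
        rec = Recording(samples=np.zeros(12), fs=100.0)
        with pytest.raises(ValueError, match="too short"):
            compute_psd(rec)


class TestSmoothSpectrum:
    def _spectrum(self, power, fs=100.0):
        power = np.asarray(power, dtype=float)
        n = power.size
        return Spectrum(freqs=np.linspace(0, fs / 2, n), power=power, fs=fs,
                        window_samples=n, fft_samples=2 * (n - 1))

    def test_width_one_is_identity(self):
        rng = np.random.default_rng(1)
        s = self._spectrum(rng.uniform(size=64))
        np.testing.assert_array_equal(smooth_spectrum(s, 1).power, s.power)

    def test_constant_preserved_including_edges(self):
        s = self._spectrum(np.full(50, 3.0))
        np.testing.assert_allclose(smooth_spectrum(s, 7).power, 3.0)

    def test_interior_impulse_spreads_uniformly(self):
        p = np.zeros(33)
        p[16] = 1.0
        out = smooth_spectrum(self._spectrum(p), 5).power
        np.testing.assert_allclose(out[14:19], 0.2)
        assert np.allclose(out[:14], 0.0) and np.allclose(out[19:], 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(size=40), rng.uniform(size=40)
        a, b = 2.5, 0.3
        lhs = smooth_spectrum(self._spectrum(a * x + b * y), 5).power
        rhs = a * smooth_spectrum(self._spectrum(x), 5).power \
            + b * smooth_spectrum(self._spectrum(y), 5).power
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    @pytest.mark.parametrize("width", [0, -3, 4])
    def test_invalid_width_rejected(self, width):
        s = self._spectrum(np.ones(16))
        with pytest.raises(ValueError):
            smooth_spectrum(s, width)


class TestBandEnergy:
    def _spectrum(self, freqs, power, fs):
        return Spectrum(freqs=np.asarray(freqs, float), power=np.asarray(power, float),
                        fs=fs, window_samples=len(freqs), fft_samples=2 * (len(freqs) - 1))

    def test_flat_spectrum_splits_evenly(self):
        s = self._spectrum(np.linspace(0, 100, 501), np.ones(501), fs=200.0)
        prof = band_energy(s, n_bands=10, f_max=100.0)
        np.testing.assert_allclose(prof.fractions, 0.1, atol=1e-9)
        assert prof.total_in_range == pytest.approx(1.0)

    def test_low_frequency_support_concentrates_first_band(self):
        freqs = np.linspace(0, 500, 2001)
        power = np.exp(-((freqs - 5.0) ** 2))
        s = self._spectrum(freqs, power, fs=1000.0)
        prof = band_energy(s)
        assert prof.fractions[0] == pytest.approx(prof.total_in_range)
        assert np.allclose(prof.fractions[1:], 0.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        freqs = np.linspace(0, 500, 1001)
        power = rng.uniform(size=1001)
        s = self._spectrum(freqs, power, fs=1000.0)
        p1 = band_energy(s).fractions
        s2 = self._spectrum(freqs, 37.5 * power, fs=1000.0)
        np.testing.assert_allclose(band_energy(s2).fractions, p1, rtol=1e-12)

    def test_fractions_sum_to_total_in_range(self):
        rng = np.random.default_rng(4)
        s = self._spectrum(np.linspace(0, 500, 1001), rng.uniform(size=1001), fs=1000.0)
        prof = band_energy(s)
        assert prof.fractions.sum() == pytest.approx(prof.total_in_range, abs=1e-9)
        assert prof.total_in_range < 1.0  # spectrum extends beyond 100 Hz

    def test_f_max_beyond_nyquist_rejected(self):
        s = self._spectrum(np.linspace(0, 50, 101), np.ones(101), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            band_energy(s, f_max=100.0)

    def test_zero_spectrum_gives_zero_profile(self):
        s = self._spectrum(np.linspace(0, 500, 101), np.zeros(101), fs=1000.0)
        prof = band_energy(s)
        assert prof.total_in_range == 0.0
        np.testing.assert_array_equal(prof.fractions, 0.0)
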
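import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcspectra import (
    Spectrum,
    assign_band,
    detect_peaks,
    hilbert_zero_cross_peaks,
    prune_harmonics,
    smooth_spectrum,
)
from conftest import make_bump_spectrum


def _spectrum(power, f_max=50.0):
    power = np.asarray(power, dtype=float)
    n = power.size
    return Spectrum(freqs=np.linspace(0, f_max, n), power=power, fs=2 * f_max,
                    window_samples=n, fft_samples=2 * (n - 1))


class TestHilbertZeroCrossPeaks:
    def test_single_lobe_gives_one_peak_at_maximum(self):
        rng = np.random.default_rng(0)
        s = smooth_spectrum(make_bump_spectrum(rng, n_bumps=1), 5)
        peaks = hilbert_zero_cross_peaks(s)
        assert len(peaks) == 1
        argmax_freq = s.freqs[np.argmax(s.power)]
        assert abs(peaks[0][0] - argmax_freq) <= s.df

    def test_monotone_decreasing_spectrum_has_no_peaks(self):
        s = _spectrum(np.linspace(1.0, 0.0, 256) ** 2)
        assert hilbert_zero_cross_peaks(s) == []

    def test_two_separated_bumps_both_found(self):
        freqs = np.linspace(0, 50, 512)
        power = (np.exp(-0.5 * ((freqs - 10) / 1.0) ** 2)
                 + 0.8 * np.exp(-0.5 * ((freqs - 30) / 1.5) ** 2) + 1e-4)
        s = smooth_spectrum(_spectrum(power), 5)
        peaks = hilbert_zero_cross_peaks(s)
        assert len(peaks) == 2
        assert abs(peaks[0][0] - 10.0) <= 2 * s.df
        assert abs(peaks[1][0] - 30.0) <= 2 * s.df

    def test_returned_peaks_are_local_maxima(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = smooth_spectrum(make_bump_spectrum(rng), 5)
            for freq, _power in hilbert_zero_cross_peaks(s):
                j = int(np.argmin(np.abs(s.freqs - freq)))
                lo, hi = max(0, j - 2), min(s.power.size, j + 3)
                assert s.power[j] >= s.power[lo:hi].max() * (1 - 1e-12)

    def test_min_freq_drops_low_candidates(self):
        freqs = np.linspace(0, 50, 512)
        power = np.exp(-0.5 * ((freqs - 0.1) / 0.05) ** 2) + 0.5 * np.exp(
            -0.5 * ((freqs - 20) / 1.0) ** 2
        )
        s = smooth_spectrum(_spectrum(power), 5)
        peaks = hilbert_zero_cross_peaks(s, min_freq=1.0)
        assert all(f >= 1.0 for f, _ in peaks)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="short"):
            hilbert_zero_cross_peaks(_spectrum(np.ones(5)))


class TestPruneHarmonics:
    def test_tonic_example_57_is_harmonic_of_28_5(self):
        kept = prune_harmonics([(28.5, 10.0), (57.0, 4.0)])
        assert kept == [(28.5, 10.0)]

    def test_burst_example_10_6_is_harmonic_of_5_3(self):
        kept = prune_harmonics([(5.3, 8.0), (10.6, 3.0)])
        assert kept == [(5.3, 8.0)]

    def test_single_peak_unchanged(self):
        assert prune_harmonics([(12.0, 1.0)]) == [(12.0, 1.0)]

    def test_non_harmonic_peaks_survive(self):
        kept = prune_harmonics([(5.0, 1.0), (12.0, 1.0)])
        assert len(kept) == 2

    def test_third_harmonic_removed_too(self):
        kept = prune_harmonics([(7.0, 3.0), (14.1, 1.0), (20.9, 0.5)])
        assert kept == [(7.0, 3.0)]

    @given(
        st.lists(
            st.tuples(st.floats(0.5, 200.0), st.floats(0.01, 10.0)),
            min_size=1, max_size=12,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_idempotent_and_keeps_lowest(self, peaks):
        once = prune_harmonics(peaks)
        assert prune_harmonics(once) == once
        assert min(f for f, _ in once) == min(f for f, _ in peaks)


class TestAssignBand:
    @pytest.mark.parametrize(
        "freq, mode, band",
        [
            (22.53, "tonic", "sodium"),
            (6.46, "tonic", "sodium"),  # slowed ataxic tonic is still sodium
            (1.52, "burst", "calcium"),
            (0.5, "unknown", "switching"),
            (4.2, "unknown", "calcium"),
            (22.0, "unknown", "sodium"),
        ],
    )
    def test_assignment_rule(self, freq, mode, band):
        assert assign_band(freq, mode) == band

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            assign_band(0.0, "tonic")

    def test_unknown_mode_label_rejected(self):
        with pytest.raises(ValueError):
            assign_band(5.0, "bursting")


class TestDetectPeaks:
    def test_dominant_fundamental_with_harmonic_series(self):
        freqs = np.linspace(0, 50, 1024)
        power = (np.exp(-0.5 * ((freqs - 5.3) / 0.3) ** 2)
                 + 0.4 * np.exp(-0.5 * ((freqs - 10.6) / 0.3) ** 2) + 1e-5)
        s = smooth_spectrum(_spectrum(power), 5)
        ps = detect_peaks(s, mode="burst")
        assert ps.band == "calcium"
        assert len(ps.peaks) == 2 and len(ps.fundamentals) == 1
        assert ps.fundamental[0] == pytest.approx(5.3, abs=2 * s.df)
        assert not ps.multiple_fundamentals

    def test_featureless_spectrum_yields_no_band(self):
        s = _spectrum(np.full(256, 1e-12))
        ps = detect_peaks(s)
        assert ps.fundamental is None and ps.band == "none"
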
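"""Power-spectral-density estimation, smoothing and band-energy profiling.

The estimator follows the standard design for 60 s membrane-potential traces:
the mean is subtracted first (no zero-frequency component), the PSD is a
Welch average over segments of one third of the signal length (Hamming
taper, 50 % overlap) and each segment is zero-padded to twice the window
length.  A rectangular (boxcar) moving-average filter smooths the spectrum
before peak detection, and the 0–100 Hz range is split into ten equal bands
whose areas under the curve — normalised by the full-band area — summarise
where the signal's energy lives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import Recording, subtract_mean

__all__ = ["Spectrum", "BandEnergyProfile", "compute_psd", "smooth_spectrum", "band_energy"]


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density on a uniform frequency grid.

    ``power`` has units signal²/Hz; ``freqs`` runs from 0 to Nyquist with
    step ``fs / fft_samples``.
    """

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    window_samples: int
    fft_samples: int
    smooth_bins: int = 1

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        power = np.asarray(self.power, dtype=np.float64)
        if freqs.shape != power.shape:
            raise ValueError("freqs and power must have the same length")
        if np.any(power < 0):
            raise ValueError("power must be nonnegative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)

    @property
    def df(self) -> float:
        """Frequency grid step in Hz."""
        return self.fs / self.fft_samples

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0


@dataclass(frozen=True)
class BandEnergyProfile:
    """Energy fractions in equal-width bands, normalised by full-band energy.

    ``fractions[i]`` is the trapezoidal area under the PSD between
    ``edges[i]`` and ``edges[i+1]`` divided by the area over the full
    [0, Nyquist] range, so ``sum(fractions) == total_in_range <= 1``.
    """

    edges: np.ndarray
    fractions: np.ndarray
    total_in_range: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        fractions = np.asarray(self.fractions, dtype=np.float64)
        if edges.size != fractions.size + 1:
            raise ValueError("need one more edge than fractions")
        if np.any(fractions < -1e-12):
            raise ValueError("fractions must be nonnegative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "fractions", fractions)

    def as_dict(self) -> dict:
        """Fractions keyed ``e_0_10`` ... style column names."""
        return {
            f"e_{int(lo)}_{int(hi)}": float(fr)
            for lo, hi, fr in zip(self.edges[:-1], self.edges[1:], self.fractions)
        }


def compute_psd(
    rec: Recording,
    window_fraction: float = 1.0 / 3.0,
    pad_factor: int = 2,
    window: str = "hamming",
    overlap: float = 0.5,
) -> Spectrum:
    """Welch PSD with window length = ``window_fraction`` of the signal.

    The signal mean is removed first, segments are tapered, zero-padded to
    ``pad_factor`` times the window length and averaged into a one-sided
    density, so the integral of the raw spectrum over [0, Nyquist]
    approximates the signal variance (Parseval) for broadband signals.

    Raises
    ------
    ValueError
        If the recording is too short for the requested window.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    n = rec.n_samples
    w = int(round(window_fraction * n))
    if w < 8:
        raise ValueError(
            f"recording of {n} samples is too short for window_fraction={window_fraction}"
        )
    nfft = int(round(pad_factor * w))
    x = subtract_mean(rec).samples
    freqs, power = sps.welch(
        x,
        fs=rec.fs,
        window=window,
        nperseg=w,
        noverlap=int(round(overlap * w)),
        nfft=nfft,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    return Spectrum(freqs=freqs, power=power, fs=rec.fs, window_samples=w, fft_samples=nfft)


def smooth_spectrum(s: Spectrum, width_bins: int = 5) -> Spectrum:
    """Rectangular moving average of odd ``width_bins``.

    Edges are handled by renormalising the truncated window, so a constant
    spectrum stays constant and the operation is linear in the power values.
    """
    if width_bins < 1 or width_bins % 2 == 0:
        raise ValueError("width_bins must be an odd positive integer")
    if width_bins > s.power.size:
        raise ValueError("width_bins exceeds the spectrum length")
    if width_bins == 1:
        return replace(s, smooth_bins=1)
    kernel = np.ones(width_bins)
    num = np.convolve(s.power, kernel, mode="same")
    den = np.convolve(np.ones_like(s.power), kernel, mode="same")
    return replace(s, power=num / den, smooth_bins=width_bins)


def _trapz_between(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear PSD over [lo, hi]."""
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, power)
    return float(np.trapezoid(vals, grid))


def band_energy(s: Spectrum, n_bands: int = 10, f_max: float = 100.0) -> BandEnergyProfile:
    """Split [0, ``f_max``] into ``n_bands`` equal bands and integrate each.

    Every band area is normalised by the area over the full [0, Nyquist]
    range, so the fractions are scale-invariant and sum to the in-range
    fraction of total energy.
    """
    if f_max > s.nyquist * (1 + 1e-9):
        raise ValueError(f"f_max={f_max} Hz exceeds the Nyquist frequency {s.nyquist} Hz")
    if n_bands < 1:
        raise ValueError("n_bands must be positive")
    total = _trapz_between(s.freqs, s.power, 0.0, s.nyquist)
    edges = np.linspace(0.0, f_max, n_bands + 1)
    if total <= 0.0:
        return BandEnergyProfile(edges=edges, fractions=np.zeros(n_bands), total_in_range=0.0)
    areas = np.array(
        [_trapz_between(s.freqs, s.power, lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    fractions = areas / total
    return BandEnergyProfile(edges=edges, fractions=fractions, total_in_range=float(fractions.sum()))
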
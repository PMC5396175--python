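"""Spectral peak detection, harmonic pruning and band assignment.

Peaks are located with the Hilbert-transform method: the discrete Hilbert
transform of the (smoothed) power sequence crosses zero from negative to
positive at spectral maxima, so those crossings are used as guides, each
snapped to the nearest local maximum of the power and refined to sub-bin
precision with a parabolic fit.  Because harmonics of a periodic firing
pattern appear as an equally spaced peak series, only the first (leftmost)
peak of each harmonic series is kept as a fundamental.  The fundamental is
then assigned to the sodium band (tonic firing), the calcium band (burst
firing), or — when the firing mode is unknown — to a literature-range
fallback: switching < 1 Hz, calcium 1–15 Hz, sodium above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .spectral import Spectrum

__all__ = [
    "PeakSet",
    "hilbert_zero_cross_peaks",
    "prune_harmonics",
    "assign_band",
    "detect_peaks",
]

BANDS = ("sodium", "calcium", "switching", "none")


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks plus the harmonic-pruned fundamentals of one spectrum."""

    peaks: list = field(default_factory=list)  # (freq Hz, power), sorted by freq
    fundamentals: list = field(default_factory=list)  # harmonic-pruned subset
    fundamental: tuple | None = None  # dominant fundamental (max power)
    band: str = "none"
    mode_used: str = "unknown"

    @property
    def multiple_fundamentals(self) -> bool:
        """True when more than one fundamental survived harmonic pruning."""
        return len(self.fundamentals) > 1


def _climb_to_local_max(p: np.ndarray, i: int, half: int = 3, max_iter: int = 1000) -> int:
    """Iterative windowed ascent from index ``i`` to a local maximum.

    Each step jumps to the argmax of ``p`` within ``i ± half``, so the walk
    is not trapped by sub-window noise ripples on a peak's flank.
    """
    for _ in range(max_iter):
        lo = max(0, i - half)
        hi = min(p.size, i + half + 1)
        j = lo + int(np.argmax(p[lo:hi]))
        if j == i:
            break
        i = j
    return i


def _is_local_max(p: np.ndarray, i: int, half: int = 2) -> bool:
    lo = max(0, i - half)
    hi = min(p.size, i + half + 1)
    return p[i] >= p[lo:hi].max()


def _prominences(p: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Topographic prominences of the local maxima at indices ``idx``:
    each peak's height above the higher of the two minima separating it
    from higher ground (or the sequence ends)."""
    if idx.size == 0:
        return np.empty(0)
    return sps.peak_prominences(p, idx)[0]


def _parabolic_refine(freqs: np.ndarray, p: np.ndarray, i: int, df: float) -> float:
    """Sub-bin peak position from a parabola through three power values."""
    if i <= 0 or i >= p.size - 1:
        return float(freqs[i])
    denom = p[i - 1] - 2.0 * p[i] + p[i + 1]
    if denom >= 0:  # flat or degenerate neighbourhood
        return float(freqs[i])
    delta = 0.5 * (p[i - 1] - p[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(freqs[i] + delta * df)


def hilbert_zero_cross_peaks(
    s: Spectrum,
    min_freq: float = 0.2,
    prominence: float = 0.05,
) -> list:
    """Locate spectral peaks at negative-to-positive Hilbert zero crossings.

    Parameters
    ----------
    s : Spectrum
        A (preferably smoothed) spectrum.
    min_freq : float
        Candidates below this frequency are dropped (suppresses the residual
        DC shoulder left after mean subtraction).
    prominence : float
        Significance floor: a candidate's topographic prominence must be
        at least this fraction of the spectrum's maximum power, otherwise
        it is treated as a noise ripple or shoulder.

    Returns
    -------
    list of (freq_hz, power)
        Sorted by frequency; every entry is a local maximum of the power
        sequence within ±2 bins, with sub-bin parabolic refinement of the
        reported frequency.
    """
    p = s.power
    if p.size < 8:
        raise ValueError("spectrum too short for peak detection (< 8 bins)")
    if min_freq >= s.nyquist:
        raise ValueError("min_freq must lie below the Nyquist frequency")
    if p.max() <= 0:
        return []
    # Remove the broad spectral baseline first: the Hilbert transform of a
    # zero-mean excursion crosses zero at each peak, whereas on the raw
    # power sequence a single dominant peak masks the crossings of its
    # neighbours.  The baseline is a wide moving average (about one tenth
    # of the spectrum, much wider than any resolved peak).
    baseline_bins = max(9, 2 * (p.size // 10) + 1)
    kernel = np.ones(baseline_bins)
    baseline = np.convolve(p, kernel, mode="same") / np.convolve(
        np.ones_like(p), kernel, mode="same"
    )
    ht = np.imag(sps.hilbert(p - baseline))
    crossings = np.nonzero((ht[:-1] < 0) & (ht[1:] >= 0))[0]
    floor = prominence * p.max()
    candidates: list[int] = []
    seen: set[int] = set()
    for c in crossings:
        j = _climb_to_local_max(p, c)
        if j in seen or j == 0 or j == p.size - 1 or s.freqs[j] < min_freq:
            continue
        seen.add(j)
        if _is_local_max(p, j):
            candidates.append(j)
    candidates = sorted(candidates)
    keep = _prominences(p, np.asarray(candidates, dtype=np.intp)) >= floor
    return [
        (_parabolic_refine(s.freqs, p, j, s.df), float(p[j]))
        for j, ok in zip(candidates, keep)
        if ok
    ]


def prune_harmonics(peaks: list, rel_tol: float = 0.05) -> list:
    """Keep only the first (leftmost) peak of each equally spaced series.

    Walking up in frequency, a peak is discarded when it lies within
    ``rel_tol * k * f0`` of an integer multiple ``k * f0`` (k >= 2) of any
    already-retained fundamental ``f0``.  Idempotent; the lowest-frequency
    peak is always retained.
    """
    if rel_tol < 0:
        raise ValueError("rel_tol must be nonnegative")
    retained: list = []
    for freq, power in sorted(peaks):
        is_harmonic = False
        for f0, _ in retained:
            k = round(freq / f0)
            if k >= 2 and abs(freq - k * f0) <= rel_tol * k * f0:
                is_harmonic = True
                break
        if not is_harmonic:
            retained.append((freq, power))
    return retained


def assign_band(fundamental_freq: float, mode: str = "unknown") -> str:
    """Assign a fundamental to the sodium / calcium / switching band.

    The firing mode is authoritative when known (tonic output shows the
    sodium peak; burst output the calcium peak).  For an unknown mode a
    literature-range fallback is used; this is second-class because slowed
    tonic peaks (e.g. in ataxic cells) can fall inside the nominal calcium
    range.
    """
    if not fundamental_freq > 0:
        raise ValueError("fundamental frequency must be positive")
    if mode == "tonic":
        return "sodium"
    if mode == "burst":
        return "calcium"
    if mode != "unknown":
        raise ValueError(f"mode must be tonic, burst or unknown, got {mode!r}")
    if fundamental_freq < 1.0:
        return "switching"
    if fundamental_freq < 15.0:
        return "calcium"
    return "sodium"


def detect_peaks(
    s: Spectrum,
    mode: str = "unknown",
    min_freq: float = 0.2,
    prominence: float = 0.05,
    rel_tol: float = 0.05,
) -> PeakSet:
    """Full peak stage: detect, prune harmonics, pick the dominant fundamental.

    The dominant fundamental is the retained peak with the highest power
    (matching peak detection "by taking the position of the maximum").
    """
    peaks = hilbert_zero_cross_peaks(s, min_freq=min_freq, prominence=prominence)
    fundamentals = prune_harmonics(peaks, rel_tol=rel_tol)
    if not fundamentals:
        return PeakSet(peaks=peaks, fundamentals=[], fundamental=None, band="none", mode_used=mode)
    dominant = max(fundamentals, key=lambda fp: fp[1])
    return PeakSet(
        peaks=peaks,
        fundamentals=fundamentals,
        fundamental=dominant,
        band=assign_band(dominant[0], mode),
        mode_used=mode,
    )
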
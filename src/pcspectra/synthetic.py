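"""Surrogate Purkinje-cell firing traces for testing the spectral pipeline.

Real PC recordings show two firing modes: tonic trains of fast sodium
spikes (fundamental roughly 6–31 Hz depending on condition) and bursting
paced by a slow calcium oscillation (fundamental roughly 0.35–7.85 Hz).
The generator reproduces the *spectral* structure of those modes — spike
trains with near-regular (Gamma-distributed) intervals, bursts of spikes
riding a slow depolarising envelope, plus white measurement noise — not
their biophysics.  Cohort presets mirror the composition and per-cell
frequency statistics of three experimental cohorts (normal, 3-AP ataxic,
riluzole + 3-AP), with per-cell fundamentals drawn from the group
mean ± SD truncated to the group's observed frequency range.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Recording

__all__ = [
    "TonicParams",
    "BurstParams",
    "CohortSpec",
    "generate_tonic",
    "generate_burst",
    "generate_cohort",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class TonicParams:
    """Parameters of a tonic sodium-spike train.

    ``cv_isi`` is the coefficient of variation of the inter-spike
    intervals; 0 gives a perfectly regular train.  Intervals are Gamma
    distributed with shape 1/cv².
    """

    f_na: float  # mean sodium-spike rate, Hz
    cv_isi: float = 0.02
    spike_amp: float = 80.0  # mV
    spike_width: float = 0.002  # s
    noise_sd: float = 0.5  # mV
    fs: float = 1000.0  # Hz
    duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.f_na > 0:
            raise ValueError("f_na must be positive")
        if not 0 <= self.cv_isi < 1:
            raise ValueError("cv_isi must lie in [0, 1)")
        if self.spike_width * self.fs < 2:
            raise ValueError(
                f"spike_width {self.spike_width}s spans fewer than 2 samples at fs={self.fs} Hz"
            )


@dataclass(frozen=True)
class BurstParams:
    """Parameters of a calcium-paced bursting trace.

    Each burst carries ``n_spikes_per_burst`` spikes at ``f_intra`` riding a
    half-sine depolarising envelope of the burst duration
    (``n_spikes_per_burst / f_intra``); bursts recur at ``f_ca`` with
    Gamma-jittered intervals (``cv_burst``).
    """

    f_ca: float  # burst rate, Hz
    n_spikes_per_burst: int = 4
    f_intra: float = 40.0  # intra-burst spike rate, Hz
    envelope_amp: float = 20.0  # mV
    spike_amp: float = 40.0  # mV
    spike_width: float = 0.002  # s
    cv_burst: float = 0.05
    noise_sd: float = 0.5  # mV
    fs: float = 1000.0  # Hz
    duration: float = 60.0  # s
    seed: int = 0

    @property
    def burst_duration(self) -> float:
        return self.n_spikes_per_burst / self.f_intra

    def __post_init__(self) -> None:
        if not self.f_ca > 0:
            raise ValueError("f_ca must be positive")
        if self.n_spikes_per_burst < 1:
            raise ValueError("n_spikes_per_burst must be at least 1")
        if not self.f_intra > self.f_ca:
            raise ValueError("f_intra must exceed the burst rate f_ca")
        if not self.burst_duration < 1.0 / self.f_ca:
            raise ValueError(
                f"burst of {self.burst_duration:g}s does not fit in the "
                f"{1.0 / self.f_ca:g}s burst cycle"
            )
        if not 0 <= self.cv_burst < 1:
            raise ValueError("cv_burst must lie in [0, 1)")
        if self.spike_width * self.fs < 2:
            raise ValueError("spike_width spans fewer than 2 samples")


@dataclass(frozen=True)
class CohortSpec:
    """Composition and per-cell frequency statistics of one cohort.

    Per-cell fundamentals are drawn from N(mean, sd²) truncated to
    ``f_na_range`` / ``f_ca_range`` (positive reals when a range is None).
    """

    cohort: str
    n_tonic: int
    n_burst: int
    f_na_mean: float
    f_na_sd: float
    f_ca_mean: float
    f_ca_sd: float
    f_na_range: tuple | None = None
    f_ca_range: tuple | None = None
    fs: float = 1000.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tonic < 0 or self.n_burst < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.f_na_sd < 0 or self.f_ca_sd < 0:
            raise ValueError("frequency SDs must be nonnegative")


#: Cohort presets: group composition (counts), per-band
#: mean ± SD and observed frequency ranges (the riluzole group has no
#: reported range, so only positivity is enforced there).
PRESETS = {
    "normal": CohortSpec(
        "normal", 7, 13, 22.53, 5.49, 4.22, 2.02,
        f_na_range=(15.05, 31.2), f_ca_range=(1.04, 7.85),
    ),
    "3ap": CohortSpec(
        "3AP", 3, 16, 6.46, 0.23, 1.52, 1.19,
        f_na_range=(6.22, 6.68), f_ca_range=(0.35, 4.57),
    ),
    "riluzole": CohortSpec(
        "riluzole_3AP", 2, 2, 31.34, 4.07, 3.88, 1.37,
    ),
}


def preset(name: str, seed: int = 0) -> CohortSpec:
    """A copy of a named cohort preset (``normal``, ``3ap``, ``riluzole``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def _spike_template(fs: float, width: float, amp: float) -> np.ndarray:
    """Stereotyped biphasic spike: fast rise, exponential decay, small AHP."""
    n = max(2, int(round(width * fs)))
    t = np.arange(3 * n) / fs
    tau_r = width / 8.0
    tau_d = width / 2.5
    wave = (1.0 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)
    wave = wave / wave.max()
    ahp = -0.15 * np.exp(-(t - t[n]) / (2.0 * width)) * (t >= t[n])
    wave = wave + ahp
    return amp * wave


def _gamma_isis(rng: np.random.Generator, rate: float, cv: float, total: float) -> np.ndarray:
    """Event times in [0, total) with Gamma-distributed inter-event intervals."""
    mean_isi = 1.0 / rate
    n_max = int(np.ceil(total * rate * 1.5)) + 20
    if cv == 0:
        times = np.arange(n_max) * mean_isi
    else:
        shape = 1.0 / cv**2
        isis = rng.gamma(shape, scale=mean_isi / shape, size=n_max)
        times = np.concatenate(([0.0], np.cumsum(isis)))
        while times[-1] < total:  # pragma: no cover - generous n_max
            extra = rng.gamma(shape, scale=mean_isi / shape, size=n_max)
            times = np.concatenate((times, times[-1] + np.cumsum(extra)))
    return times[times < total]


def _add_at(signal: np.ndarray, template: np.ndarray, idx: int) -> None:
    stop = min(signal.size, idx + template.size)
    if stop > idx >= 0:
        signal[idx:stop] += template[: stop - idx]


def _realized_rate(times: np.ndarray, duration: float) -> float:
    """Empirical fundamental: reciprocal of the mean inter-event interval."""
    if times.size < 2:
        return times.size / duration
    return (times.size - 1) / (times[-1] - times[0])


def generate_tonic(p: TonicParams) -> Recording:
    """Synthesize a tonic sodium-spike train.

    The trace is a sum of stereotyped spike waveforms at Gamma-renewal
    times plus white Gaussian noise.  Metadata records the target rate and
    the realized rate (1 / mean inter-spike interval) actually present in
    the trace.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    x = np.zeros(n)
    times = _gamma_isis(rng, p.f_na, p.cv_isi, p.duration)
    template = _spike_template(p.fs, p.spike_width, p.spike_amp)
    for t in times:
        _add_at(x, template, int(round(t * p.fs)))
    if p.noise_sd > 0:
        x += rng.normal(0.0, p.noise_sd, size=n)
    return Recording(
        samples=x,
        fs=p.fs,
        cohort="synthetic",
        mode="tonic",
        meta={
            "f_target": p.f_na,
            "f_realized": _realized_rate(times, p.duration),
            "n_spikes": int(times.size),
            "params": p,
        },
    )


def generate_burst(p: BurstParams) -> Recording:
    """Synthesize a calcium-paced bursting trace.

    Burst onsets follow a Gamma renewal process at ``f_ca``; each burst is
    a half-sine depolarising envelope carrying ``n_spikes_per_burst``
    spikes at ``f_intra``.  With one spike per burst the trace degenerates
    to a tonic-like train at ``f_ca``.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    x = np.zeros(n)
    onsets = _gamma_isis(rng, p.f_ca, p.cv_burst, p.duration)
    template = _spike_template(p.fs, p.spike_width, p.spike_amp)
    n_env = max(2, int(round(p.burst_duration * p.fs)))
    envelope = p.envelope_amp * np.sin(np.pi * np.arange(n_env) / (n_env - 1))
    for onset in onsets:
        _add_at(x, envelope, int(round(onset * p.fs)))
        for j in range(p.n_spikes_per_burst):
            _add_at(x, template, int(round((onset + j / p.f_intra) * p.fs)))
    if p.noise_sd > 0:
        x += rng.normal(0.0, p.noise_sd, size=n)
    return Recording(
        samples=x,
        fs=p.fs,
        cohort="synthetic",
        mode="burst",
        meta={
            "f_target": p.f_ca,
            "f_realized": _realized_rate(onsets, p.duration),
            "n_bursts": int(onsets.size),
            "params": p,
        },
    )


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple | None
) -> float:
    """Rejection-sample N(mean, sd²) truncated to ``bounds`` (or > 0)."""
    lo, hi = bounds if bounds is not None else (0.0, np.inf)
    for _ in range(10000):
        f = rng.normal(mean, sd)
        if lo < f <= hi or (bounds is None and f > 0):
            return float(f)
    raise RuntimeError("truncated draw failed; check mean/sd against bounds")


def generate_cohort(spec: CohortSpec) -> list:
    """Generate ``n_tonic + n_burst`` recordings for one cohort.

    Per-cell fundamentals are drawn from the cohort's truncated normal
    distributions; each cell gets an independent child seed so the whole
    cohort is reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    recs: list = []
    for i in range(spec.n_tonic):
        f = _draw_truncated(rng, spec.f_na_mean, spec.f_na_sd, spec.f_na_range)
        p = TonicParams(
            f_na=f, fs=spec.fs, duration=spec.duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = generate_tonic(p)
        recs.append(
            replace(rec, cohort=spec.cohort, meta={**rec.meta, "cell_id": f"{spec.cohort}_t{i}"})
        )
    for i in range(spec.n_burst):
        f = _draw_truncated(rng, spec.f_ca_mean, spec.f_ca_sd, spec.f_ca_range)
        p = BurstParams(
            f_ca=f, fs=spec.fs, duration=spec.duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = generate_burst(p)
        recs.append(
            replace(rec, cohort=spec.cohort, meta={**rec.meta, "cell_id": f"{spec.cohort}_b{i}"})
        )
    return recs
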
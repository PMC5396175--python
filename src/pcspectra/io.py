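"""Reading, writing, segmenting and preprocessing of membrane-potential traces.

A trace is a uniformly sampled time series (membrane potential in mV, or
model units) carried by :class:`Recording` together with its sampling rate,
cohort label (``normal``, ``3AP``, ``riluzole_3AP``, ``model``, ``synthetic``)
and firing-mode label (``tonic``, ``burst``, ``unknown``).

File dialect: plain delimited text (whitespace or comma), one trace per file,
optional ``#`` comment header.  Two columns are interpreted as (time s,
signal mV); one column is the signal alone and requires an explicit sampling
rate.  ``write_recording`` stores the sampling rate and labels in the header
so a round trip is lossless.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "ParseError",
    "SamplingError",
    "read_recording",
    "write_recording",
    "take_segment",
    "subtract_mean",
]

COHORTS = ("normal", "3AP", "riluzole_3AP", "model", "synthetic")
MODES = ("tonic", "burst", "unknown")

#: any time step may deviate from the median step by at most this relative amount
FS_TOLERANCE = 1e-3


class ParseError(ValueError):
    """Raised when a trace file cannot be parsed as numeric columns."""


class SamplingError(ValueError):
    """Raised when time stamps are not uniform within tolerance."""


@dataclass(frozen=True)
class Recording:
    """A uniformly sampled single-channel trace.

    Parameters
    ----------
    samples : ndarray
        Signal values (mV for experimental-style traces).  Must be finite
        and contain at least two samples.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    cohort, mode : str
        Provenance labels; see :data:`COHORTS` and :data:`MODES`.
    meta : dict
        Free-form provenance (generator parameters, cell id, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    cohort: str = "synthetic"
    mode: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("a recording needs at least two samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs


_HEADER_RE = re.compile(r"#\s*(\w+)\s*=\s*(\S+)")


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.lstrip().startswith("#"):
                break
            m = _HEADER_RE.search(line)
            if m:
                meta[m.group(1)] = m.group(2)
    return meta


def read_recording(path, fs: float | None = None) -> Recording:
    """Read a delimited-text trace.

    One numeric column is taken as the signal (``fs`` must then be given,
    either as an argument or as a ``# fs_hz = ...`` header line).  Two
    columns are (time s, signal); the sampling rate is inferred from the
    median time step and every step must agree with it to within 0.1 %.
    """
    path = Path(path)
    header = _parse_header(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-input warning
            data = np.loadtxt(
                path, comments="#", delimiter=None if _is_whitespace(path) else ",", ndmin=2
            )
    except ValueError as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if data.size == 0:
        raise ParseError(f"{path} contains no data rows")

    header_fs = float(header["fs_hz"]) if "fs_hz" in header else None
    if data.shape[1] == 1:
        samples = data[:, 0]
        eff_fs = fs if fs is not None else header_fs
        if eff_fs is None:
            raise ValueError("single-column trace requires an explicit sampling rate")
        t0 = float(header.get("t0_s", 0.0))
    elif data.shape[1] == 2:
        t, samples = data[:, 0], data[:, 1]
        steps = np.diff(t)
        med = float(np.median(steps))
        if med <= 0:
            raise SamplingError("time stamps must be strictly increasing")
        if np.any(np.abs(steps - med) > FS_TOLERANCE * med):
            raise SamplingError(
                "non-uniform sampling: a time step deviates from the median "
                f"step {med:g} s by more than {FS_TOLERANCE:.0e} relative"
            )
        eff_fs = fs if fs is not None else (header_fs if header_fs is not None else 1.0 / med)
        t0 = float(t[0])
    else:
        raise ParseError(f"{path} has {data.shape[1]} columns; expected 1 or 2")

    return Recording(
        samples=samples,
        fs=float(eff_fs),
        t0=t0,
        cohort=header.get("cohort", "synthetic"),
        mode=header.get("mode", "unknown"),
        meta={"source": str(path)},
    )


def _is_whitespace(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                return "," not in line
    return True


def write_recording(rec: Recording, path) -> None:
    """Write a two-column (time, signal) trace with a metadata header."""
    path = Path(path)
    header = (
        f"pcspectra trace\n"
        f"fs_hz = {rec.fs!r}\n"
        f"t0_s = {rec.t0!r}\n"
        f"cohort = {rec.cohort}\n"
        f"mode = {rec.mode}"
    )
    np.savetxt(
        path,
        np.column_stack([rec.times, rec.samples]),
        fmt="%.17g",
        header=header,
    )


def take_segment(rec: Recording, start_s: float, length_s: float) -> Recording:
    """Extract a segment of ``length_s`` seconds starting at ``start_s``.

    The segment must lie fully inside the recording; the sampling rate and
    all labels are preserved.
    """
    n = int(round(length_s * rec.fs))
    i0 = int(round(start_s * rec.fs))
    if n < 1:
        raise ValueError("segment length must be at least one sample")
    if i0 < 0 or i0 + n > rec.samples.size:
        raise ValueError(
            f"segment [{start_s}, {start_s + length_s}) s exceeds the "
            f"{rec.duration:g} s recording"
        )
    return replace(rec, samples=rec.samples[i0 : i0 + n], t0=rec.t0 + i0 / rec.fs)


def subtract_mean(rec: Recording) -> Recording:
    """Remove the signal mean (suppresses the zero-frequency component)."""
    return replace(rec, samples=rec.samples - rec.samples.mean())
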
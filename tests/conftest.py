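import numpy as np
import pytest

from pcspectra import Recording, Spectrum


@pytest.fixture
def sine_recording():
    """60 s of a pure 10 Hz tone at 1 kHz (10 Hz lies exactly on the PSD grid)."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    return Recording(samples=np.sin(2 * np.pi * 10.0 * t), fs=fs)


@pytest.fixture
def noise_recording():
    rng = np.random.default_rng(42)
    return Recording(samples=rng.normal(0.0, 1.0, 60_000), fs=1000.0)


def make_bump_spectrum(rng, nbins=512, f_max=50.0, n_bumps=None):
    """Random sum of 1-4 Gaussian bumps plus a small noise floor."""
    freqs = np.linspace(0.0, f_max, nbins)
    power = np.zeros(nbins)
    if n_bumps is None:
        n_bumps = int(rng.integers(1, 5))
    for _ in range(n_bumps):
        c = rng.uniform(3.0, 0.9 * f_max)
        w = rng.uniform(0.5, 3.0)
        a = rng.uniform(0.3, 1.0)
        power += a * np.exp(-0.5 * ((freqs - c) / w) ** 2)
    power += rng.uniform(0.0, 0.01, nbins)
    return Spectrum(
        freqs=freqs, power=power, fs=2 * f_max,
        window_samples=nbins, fft_samples=2 * (nbins - 1),
    )
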
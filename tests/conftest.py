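import numpy as np
import pytest

from cardioscreen import SimConfig, simulate_cohort
from cardioscreen.detector import precompute_features
from cardioscreen.preprocess import PreprocConfig


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 synthetic patients with audio; shared across detector-level tests."""
    return simulate_cohort(SimConfig(n_patients=24, seed=5))


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return precompute_features(tiny_cohort, PreprocConfig())


@pytest.fixture(scope="session")
def echo_cohort_1200():
    """Echo-only cohort (no audio) for allocation experiments."""
    return simulate_cohort(SimConfig(n_patients=1200, seed=42), render_audio=False)


def band_rms(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """RMS of a waveform restricted to a frequency band (FFT mask)."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    return float(np.sqrt(np.mean(np.fft.irfft(spec, n=x.size) ** 2)))
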
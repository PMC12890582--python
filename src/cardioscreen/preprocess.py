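"""Recording preprocessing: spike removal, unit rescaling, z-normalised log-Mel spectrogram.

The chain mirrors standard phonocardiogram practice: friction/contact spikes
are removed with a Schmidt-style median-of-window-maxima rule, the waveform
is rescaled to unit peak amplitude, and a log-Mel power spectrogram is
z-scored per Mel bin over time.  Per-bin z-scoring both boosts the relative
energy of the quiet high-frequency murmur bands and cancels any fixed
per-frequency colouration introduced by a particular stethoscope (a device
transfer function is an additive per-bin offset in log power).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .cohort import Recording, Site

__all__ = [
    "PreprocConfig",
    "MelSpectrogram",
    "remove_spikes",
    "normalise_amplitude",
    "mel_znorm",
    "preprocess_recording",
    "mel_filterbank",
]


@dataclass(frozen=True)
class PreprocConfig:
    fs_target: float = 4000.0
    spike_window: float = 0.5  # s
    spike_factor: float = 3.0  # threshold multiplier on the median window maximum
    n_mels: int = 64
    window_length: float = 0.025  # s, Hann
    hop_length: float = 0.010  # s
    fmin: float = 20.0
    fmax: float = 1000.0
    n_fft: int = 256  # zero-padded FFT length; must cover the window
    log_floor: float = 1e-10
    znorm_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.fmax > self.fs_target / 2:
            raise ValueError("fmax must not exceed the Nyquist frequency")
        if self.hop_length > self.window_length:
            raise ValueError("hop_length must not exceed window_length")
        for name in ("fs_target", "spike_window", "spike_factor", "n_mels", "window_length",
                     "hop_length", "fmin", "fmax", "log_floor", "znorm_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MelSpectrogram:
    """Z-scored log-Mel power matrix (n_mels x T) with frame times in seconds."""

    values: np.ndarray
    frame_times: np.ndarray
    site: Site | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def remove_spikes(w: np.ndarray, fs: float, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Schmidt-style spike removal.

    The waveform is divided into consecutive windows (default 0.5 s); while
    the largest per-window maximum absolute amplitude exceeds
    ``spike_factor`` times the median of those maxima, the offending spike
    sample and its neighbourhood out to the nearest zero-crossings are
    zeroed.  Output length equals input length and the global maximum
    absolute amplitude never increases.
    """
    cfg = cfg or PreprocConfig()
    w = np.asarray(w, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty waveform")
    out = w.copy()
    win = max(int(round(cfg.spike_window * fs)), 1)
    n_win = max(out.size // win, 1)
    bounds = [(i * win, (i + 1) * win if i < n_win - 1 else out.size) for i in range(n_win)]
    maxima = np.array([np.max(np.abs(out[a:b])) for a, b in bounds])
    for _ in range(10_000):
        med = np.median(maxima)
        top = int(np.argmax(maxima))
        if med <= 0 or maxima[top] <= cfg.spike_factor * med:
            break
        a, b = bounds[top]
        seg = out[a:b]
        spike = a + int(np.argmax(np.abs(seg)))
        sign = np.signbit(out)
        left = spike
        while left > a and sign[left - 1] == sign[spike] and out[left - 1] != 0.0:
            left -= 1
        right = spike
        while right < b - 1 and sign[right + 1] == sign[spike] and out[right + 1] != 0.0:
            right += 1
        out[left : right + 1] = 0.0
        maxima[top] = np.max(np.abs(out[a:b]))
    return out


def normalise_amplitude(w: np.ndarray) -> np.ndarray:
    """Rescale to unit peak absolute amplitude; an identically-zero waveform
    is returned unchanged."""
    w = np.asarray(w, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty waveform")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform contains non-finite samples")
    peak = np.max(np.abs(w))
    if peak == 0.0:
        return w.copy()
    return w / peak


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float, fmin: float, fmax: float) -> np.ndarray:
    """Triangular Mel filterbank (HTK mel scale), shape (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_znorm(w: np.ndarray, fs: float, cfg: PreprocConfig | None = None,
              site: Site | None = None) -> MelSpectrogram:
    """Log-Mel power spectrogram, z-scored per Mel bin over time.

    Frame count follows T = 1 + floor((n - window) / hop).  Each bin has
    time-mean 0; bins with non-degenerate variance have time-std 1 (an
    epsilon in the denominator keeps constant bins finite and ~0).
    """
    cfg = cfg or PreprocConfig()
    w = np.asarray(w, dtype=np.float64)
    win = int(round(cfg.window_length * fs))
    hop = int(round(cfg.hop_length * fs))
    if w.size < win:
        raise ValueError("recording shorter than one analysis window")
    n_frames = 1 + (w.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = w[idx] * sps.get_window("hann", win, fftbins=True)[None, :]
    n_fft = max(cfg.n_fft, win)  # zero-pad for a finer frequency grid
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2  # (T, n_fft//2+1)
    fb = mel_filterbank(cfg.n_mels, n_fft, fs, cfg.fmin, cfg.fmax)
    mel = power @ fb.T  # (T, n_mels)
    logmel = np.log10(np.maximum(mel, cfg.log_floor))
    mean = logmel.mean(axis=0, keepdims=True)
    std = logmel.std(axis=0, keepdims=True)
    z = (logmel - mean) / (std + cfg.znorm_epsilon)
    frame_times = (np.arange(n_frames) * hop + win / 2) / fs
    return MelSpectrogram(values=z.T.astype(np.float64), frame_times=frame_times, site=site)


def preprocess_recording(r: Recording, cfg: PreprocConfig | None = None) -> MelSpectrogram:
    """Full chain: resample (if needed) -> remove spikes -> unit amplitude -> z-scored log-Mel."""
    cfg = cfg or PreprocConfig()
    w = np.asarray(r.samples, dtype=np.float64)
    fs = r.fs
    if fs != cfg.fs_target:
        frac = Fraction(cfg.fs_target / fs).limit_denominator(1000)
        w = sps.resample_poly(w, frac.numerator, frac.denominator)
        fs = cfg.fs_target
    if w.size < 0.5 * fs:
        raise ValueError("recordings shorter than 0.5 s are rejected")
    w = remove_spikes(w, fs, cfg)
    w = normalise_amplitude(w)
    return mel_znorm(w, fs, cfg, site=r.site)
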
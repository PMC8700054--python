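"""Mel-frequency cepstral coefficients with a swept pre-emphasis stage.

Standard MFCC chain: pre-emphasis -> framing -> Hamming window -> magnitude-
squared FFT -> triangular mel filterbank -> log -> orthonormal type-II DCT.
The pre-emphasis coefficient alpha (the first-order high-pass
y[n] = x[n] - alpha*x[n-1]) is the swept parameter: running the chain at 40
alpha values from 0.22 to 1.00 produces 40 differently filtered cepstral
views of the same clip, the MFCC analogue of the LPC order sweep.

Per clip and alpha the frame-by-cepstra matrix is flattened time-major and
cut to a fixed feature length (10240 by default) so that all feature vectors
share one geometry.  The filterbank and DCT are implemented on scipy.fft
primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, rfft

from .audio_io import AudioClip, hamming_window

LOG_FLOOR = 1e-12
DEFAULT_TARGET_LEN = 10240


def hz_to_mel(f):
    """Perceptual mel scale, mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclass(frozen=True)
class MFCCConfig:
    """MFCC chain parameters.

    Defaults are canonical speech-processing values scaled to a 44.1 kHz
    bandwidth: 2048-sample frames with 50% hop, 26 mel filters between 0 Hz
    and Nyquist, 13 retained cepstra.
    """

    pre_emphasis: float = 0.97
    frame_len: int = 2048
    hop_len: int = 1024
    n_mels: int = 26
    n_cepstra: int = 13
    fmin: float = 0.0
    fmax: float | None = None  # None = Nyquist at use time
    target_len: int = DEFAULT_TARGET_LEN

    def __post_init__(self) -> None:
        if not 0.0 <= self.pre_emphasis <= 1.0:
            raise ValueError("pre_emphasis must lie in [0, 1]")
        if self.hop_len > self.frame_len:
            raise ValueError("hop_len must be <= frame_len")
        if self.n_cepstra > self.n_mels:
            raise ValueError("n_cepstra must be <= n_mels")

    def resolved_fmax(self, rate: float) -> float:
        fmax = rate / 2 if self.fmax is None else self.fmax
        if fmax > rate / 2:
            raise ValueError(f"fmax {fmax} exceeds Nyquist {rate / 2}")
        return fmax


@dataclass(frozen=True)
class MFCCMatrix:
    """Frame-major cepstral matrix (n_frames x n_cepstra) with its config."""

    coeffs: np.ndarray
    config: MFCCConfig = field(repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("MFCC coefficients must be finite")


def pre_emphasis(x: np.ndarray, alpha: float) -> np.ndarray:
    """First-order high-pass y[n] = x[n] - alpha*x[n-1], y[0] = x[0]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    x = np.asarray(x, dtype=np.float64)
    y = x.copy()
    y[1:] -= alpha * x[:-1]
    return y


def mel_filterbank(
    n_mels: int, n_fft: int, rate: float, fmin: float, fmax: float
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Filter m rises from mel point m to m+1 and falls to m+2 on the
    mel-spaced grid; every FFT bin strictly inside (fmin, fmax) gets
    non-zero weight in at least one filter.
    """
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_mels, bin_freqs.size))
    for m in range(n_mels):
        left, center, right = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - left) / max(center - left, 1e-12)
        down = (right - bin_freqs) / max(right - center, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _frame(x: np.ndarray, frame_len: int, hop_len: int) -> np.ndarray:
    n_frames = 1 + (x.size - frame_len) // hop_len
    return sliding_window_view(x, frame_len)[:: hop_len][:n_frames]


def mfcc_matrix(clip: AudioClip, config: MFCCConfig = MFCCConfig()) -> MFCCMatrix:
    """Run the framed MFCC chain on a (pre-emphasized) clip."""
    x = clip.samples
    if x.size < config.frame_len:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one frame ({config.frame_len})"
        )
    fmax = config.resolved_fmax(clip.rate)
    frames = _frame(x, config.frame_len, config.hop_len)
    windowed = frames * hamming_window(config.frame_len)
    power = np.abs(rfft(windowed, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, config.frame_len, clip.rate, config.fmin, fmax)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    cepstra = dct(log_e, type=2, norm="ortho", axis=1)[:, : config.n_cepstra]
    return MFCCMatrix(coeffs=cepstra, config=config)


def mfcc_feature(
    clip: AudioClip, alpha: float, config: MFCCConfig = MFCCConfig()
) -> np.ndarray:
    """Fixed-length MFCC feature vector of a clip at pre-emphasis alpha.

    Applies pre-emphasis, computes the cepstral matrix, flattens it
    time-major (frame 0's cepstra first) and truncates — or zero-pads — to
    ``config.target_len``.  Truncation keeps the earliest frames.
    """
    from dataclasses import replace as _dc_replace

    emphasized = _dc_replace(clip, samples=pre_emphasis(clip.samples, alpha))
    mat = mfcc_matrix(emphasized, config)
    flat = mat.coeffs.ravel()
    if flat.size >= config.target_len:
        return flat[: config.target_len].copy()
    return np.concatenate([flat, np.zeros(config.target_len - flat.size)])


__all__ = [
    "MFCCConfig",
    "MFCCMatrix",
    "hz_to_mel",
    "mel_to_hz",
    "pre_emphasis",
    "mel_filterbank",
    "mfcc_matrix",
    "mfcc_feature",
    "DEFAULT_TARGET_LEN",
]
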
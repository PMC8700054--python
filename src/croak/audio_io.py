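"""Reading, writing and standardizing labelled audio clips.

The pipeline's unit of raw input is the :class:`AudioClip`: a mono,
finite-valued waveform with its sampling rate and a 1-based species label.
Field recordings arrive as WAV files of varying rate, duration and channel
count; :func:`standardize` maps them all onto the canonical analysis grid
(44100 Hz, 20 s by default) so that every downstream feature vector has the
same length and comparable amplitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger("croak")

#: Canonical sampling rate of the analysis pipeline, Hz.
DEFAULT_RATE = 44100
#: Canonical clip duration, seconds.
DEFAULT_DURATION = 20.0


@dataclass(frozen=True)
class AudioClip:
    """A labelled mono waveform.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitude sequence, finite, length >= 1.
    rate : float
        Sampling frequency in Hz, > 0.
    species_index : int
        1-based species label.
    clip_id : str
        Opaque identifier (file stem or generator tag).
    """

    samples: np.ndarray
    rate: float
    species_index: int
    clip_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain NaN or Inf")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.rate


def read_clip(path: str | Path, species_index: int) -> AudioClip:
    """Read a WAV file into an :class:`AudioClip`.

    Multi-channel input is averaged to mono; integer PCM is scaled to
    [-1, 1) by the type's full-scale value.  The file's native rate is kept.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty audio in {path}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples, float(rate), species_index, clip_id=path.stem)


def write_clip(clip: AudioClip, path: str | Path, subtype: str = "pcm16") -> None:
    """Write a clip as RIFF WAV, 16-bit PCM (default) or float32."""
    path = Path(path)
    if subtype == "pcm16":
        peak = np.max(np.abs(clip.samples))
        x = clip.samples / peak if peak > 1.0 else clip.samples
        data = np.round(x * 32767.0).astype(np.int16)
    elif subtype == "float":
        data = clip.samples.astype(np.float32)
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")
    wavfile.write(path, int(round(clip.rate)), data)


def standardize(
    clip: AudioClip,
    target_rate: float = DEFAULT_RATE,
    target_duration: float = DEFAULT_DURATION,
) -> AudioClip:
    """Resample, fix the length, and peak-normalize a clip.

    The output has exactly ``round(target_rate * target_duration)`` samples:
    longer clips are truncated, shorter ones zero-padded at the end.
    Resampling is band-limited (polyphase).  The result is scaled so that
    max |sample| = 1; an all-zero clip is returned unchanged in amplitude
    with a logged warning.
    """
    if target_rate <= 0 or target_duration <= 0:
        raise ValueError("target_rate and target_duration must be positive")
    x = clip.samples
    if clip.rate != target_rate:
        frac = Fraction(target_rate / clip.rate).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    n_target = int(round(target_rate * target_duration))
    if x.size >= n_target:
        x = x[:n_target]
    else:
        x = np.concatenate([x, np.zeros(n_target - x.size)])
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    else:
        logger.warning("standardize: all-zero clip %r left unnormalized", clip.clip_id)
    return replace(clip, samples=x, rate=float(target_rate))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest CSV with columns path,species_index,species_name."""
    df = pd.read_csv(path)
    required = {"path", "species_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def load_corpus(manifest_path: str | Path) -> list[AudioClip]:
    """Read every clip listed in a manifest; relative paths resolve against it."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    clips = []
    for row in df.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        clips.append(read_clip(p, int(row.species_index)))
    return clips


def _n_samples(rate: float, duration: float) -> int:
    return int(round(rate * duration))


def hamming_window(n: int) -> np.ndarray:
    """Periodic-symmetric Hamming window of length n."""
    return np.hamming(n) if n > 1 else np.ones(max(n, 0))


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        raise FloatingPointError(f"non-finite values in {what}")


__all__ = [
    "AudioClip",
    "DEFAULT_RATE",
    "DEFAULT_DURATION",
    "read_clip",
    "write_clip",
    "standardize",
    "read_manifest",
    "load_corpus",
    "hamming_window",
]
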
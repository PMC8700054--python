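"""Linear predictive coding: all-pole modelling and spectral-envelope features.

LPC models a sample as a linear combination of its P predecessors,
L_hat[k] = sum_m a_m L[k-m].  Minimizing the mean-squared prediction error
over the (windowed) clip gives the Toeplitz normal equations R a = r, solved
here by the Levinson-Durbin recursion.  The prediction coefficients define an
all-pole synthesis filter

    H(z) = G / (1 + sum_j A_j z^-j),      A_j = -a_j,

whose magnitude on the unit circle is the spectral envelope — a smooth summary
of the clip's spectrum.  The feature vector of a clip is this envelope in dB,
sampled at F uniform frequencies over [0, Nyquist); sweeping the prediction
order P from 22 to 100 produces the envelope family that forms the LPC
feature dataset.

The clip is analysed whole (one Hamming window over the full ~20 s) rather
than frame-wise: each (clip, P) pair yields exactly one length-F envelope,
which is the dataset geometry the sweep requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioClip, hamming_window

#: Magnitude floor applied before taking logs, keeps envelopes finite.
MAG_FLOOR = 1e-12
#: Default number of envelope sample points per coefficient setting.
DEFAULT_N_POINTS = 10240


@dataclass(frozen=True)
class LPCModel:
    """All-pole model of one windowed clip.

    predictor_coeffs a_1..a_P follow the predictor convention
    L_hat[k] = sum a_m L[k-m]; denominator_coeffs A_j = -a_j make the
    transfer-function denominator 1 + sum A_j z^-j literal.  gain is the
    unit-variance-excitation gain G = sqrt(error_power).
    """

    order: int
    predictor_coeffs: np.ndarray
    denominator_coeffs: np.ndarray
    gain: float
    error_power: float
    reflection_coeffs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.predictor_coeffs) != self.order:
            raise ValueError("predictor_coeffs length must equal order")
        if self.error_power < 0:
            raise ValueError("error_power must be >= 0")


@dataclass(frozen=True)
class SpectralEnvelope:
    """Sampled all-pole envelope: magnitudes in dB on a uniform Hz grid."""

    values: np.ndarray
    freq_grid: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.freq_grid):
            raise ValueError("values and freq_grid must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation r_m = sum_n x[n] x[n+m] for m = 0..max_lag.

    Computed via FFT (O(N log N)); for the ~10^6-sample clips handled here a
    direct lag-by-lag sum would be two orders of magnitude slower.
    """
    x = np.asarray(x, dtype=np.float64)
    if max_lag >= x.size:
        raise ValueError(f"max_lag {max_lag} must be < signal length {x.size}")
    nfft = 1
    while nfft < 2 * x.size:
        nfft <<= 1
    spectrum = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spectrum * np.conj(spectrum), nfft)[: max_lag + 1]
    return r.real


def levinson_durbin(r: np.ndarray, order: int) -> LPCModel:
    """Solve the LPC normal equations by the Levinson-Durbin recursion.

    Returns the order-P predictor minimizing mean-squared prediction error
    for the Toeplitz system built from autocorrelation ``r``.  The
    autocorrelation method guarantees reflection-coefficient magnitudes < 1
    (minimum-phase model); a magnitude >= 1 indicates an ill-conditioned
    input and raises.
    """
    r = np.asarray(r, dtype=np.float64)
    if len(r) < order + 1:
        raise ValueError(f"need at least order+1={order + 1} autocorrelation lags")
    if r[0] <= 0:
        raise ValueError("degenerate signal: zero-lag autocorrelation r_0 <= 0")
    a = np.zeros(order)  # predictor coefficients a_1..a_P
    err = float(r[0])
    reflections = np.zeros(order)
    for m in range(1, order + 1):
        acc = r[m] - np.dot(a[: m - 1], r[m - 1 : 0 : -1])
        k = acc / err
        if abs(k) >= 1.0:
            raise ArithmeticError(
                f"Levinson-Durbin stage {m}: reflection magnitude {abs(k):.6f} >= 1 "
                "(numerically singular autocorrelation)"
            )
        reflections[m - 1] = k
        a_new = a.copy()
        a_new[m - 1] = k
        if m > 1:
            a_new[: m - 1] = a[: m - 1] - k * a[m - 2 :: -1]
        a = a_new
        err *= 1.0 - k * k
    return LPCModel(
        order=order,
        predictor_coeffs=a,
        denominator_coeffs=-a,
        gain=float(np.sqrt(err)),
        error_power=err,
        reflection_coeffs=reflections,
    )


def spectral_envelope(
    model: LPCModel, n_points: int = DEFAULT_N_POINTS, rate: float = 44100.0
) -> SpectralEnvelope:
    """Evaluate |H| in dB at n_points uniform frequencies over [0, Nyquist).

    values[i] = 20 log10(G / |1 + sum_j A_j exp(-i j w_i)|) at
    w_i = pi * i / F.  The denominator polynomial is evaluated with one
    zero-padded FFT of length 2F.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    denom = np.zeros(2 * n_points)
    denom[0] = 1.0
    denom[1 : model.order + 1] = model.denominator_coeffs
    # rfft over 2F points samples exactly w = pi*i/F for i = 0..F
    mag = np.abs(np.fft.rfft(denom))[:n_points]
    mag = np.maximum(mag, MAG_FLOOR)
    gain = max(model.gain, MAG_FLOOR)
    values = 20.0 * np.log10(gain / mag)
    freq_grid = np.arange(n_points) * (rate / 2) / n_points
    return SpectralEnvelope(values=values, freq_grid=freq_grid)


def lpc_feature(
    clip: AudioClip, order: int, n_points: int = DEFAULT_N_POINTS
) -> np.ndarray:
    """Length-F envelope feature vector of a standardized clip at order P."""
    model = fit_lpc(clip, order)
    return spectral_envelope(model, n_points, clip.rate).values


def fit_lpc(clip: AudioClip, order: int) -> LPCModel:
    """Hamming-window the whole clip and fit the order-P all-pole model."""
    x = clip.samples * hamming_window(clip.samples.size)
    r = autocorrelation(x, order)
    return levinson_durbin(r, order)


def fit_lpc_sweep(clip: AudioClip, orders: list[int]) -> list[LPCModel]:
    """Fit every order in a sweep from one shared autocorrelation pass."""
    x = clip.samples * hamming_window(clip.samples.size)
    r = autocorrelation(x, max(orders))
    return [levinson_durbin(r, p) for p in orders]


__all__ = [
    "LPCModel",
    "SpectralEnvelope",
    "autocorrelation",
    "levinson_durbin",
    "spectral_envelope",
    "fit_lpc",
    "fit_lpc_sweep",
    "lpc_feature",
    "DEFAULT_N_POINTS",
    "MAG_FLOOR",
]
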
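"""De-shape short-time Fourier transform (dsSTFT) for low-frequency series.

A sawtooth (or any non-sinusoidal oscillation) smears energy across all of
its harmonics in a plain STFT, which makes a time-frequency map hard to read.
The de-shape transform suppresses the harmonics and keeps only the
fundamental instantaneous frequency: per frame, the short-time cepstrum of
the magnitude spectrum (|STFT|^gamma inverse-transformed over frequency) has
peaks at the oscillation period and its multiples; evaluating the
soft-thresholded cepstrum at quefrency 1/f and multiplying it with |STFT|
cancels energy at 2 f0, 3 f0, ... (whose quefrencies 1/(2 f0), ... carry no
cepstral peak) while reinforcing f0.

Defaults target 4 Hz PTT series: a 400 s Hann window resolves a 0.01 Hz
fundamental with four cycles in view; the output frequency grid spans
0.004-0.15 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _detrend
from scipy.signal import get_window

from .core import TFRepresentation

__all__ = [
    "DsstftParams",
    "StftFrames",
    "stft",
    "short_time_cepstrum",
    "deshape",
    "dsstft",
    "stft_magnitude_tf",
    "extract_ridge",
]


@dataclass
class DsstftParams:
    """Tunable de-shape STFT parameters (times in seconds)."""

    window_length: float = 400.0
    hop: float = 10.0
    gamma: float = 0.3
    cepstral_threshold: float = 0.9
    freq_range: tuple[float, float] = (0.004, 0.15)
    freq_bins: int = 512

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.gamma >= 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0 <= self.cepstral_threshold < 1:
            raise ValueError("cepstral_threshold must be a quantile in [0, 1)")
        cycles = self.window_length * self.freq_range[0]
        if cycles < 1:
            raise ValueError(
                "window must span at least one cycle of the lowest frequency"
            )
        if cycles < 2:
            warnings.warn(
                f"window holds only {cycles:.2f} cycles of the lowest "
                "frequency; estimates near the bottom of the band are "
                "unreliable",
                stacklevel=2,
            )
        if self.hop <= 0 or self.window_length <= 0:
            raise ValueError("window_length and hop must be positive")
        if self.freq_bins < 8:
            raise ValueError("freq_bins too small")

    def out_freqs(self) -> np.ndarray:
        return np.linspace(self.freq_range[0], self.freq_range[1], self.freq_bins)


@dataclass
class StftFrames:
    """Complex STFT frames on the internal (zero-padded FFT) frequency grid."""

    times: np.ndarray
    freqs: np.ndarray
    frames: np.ndarray  # complex, [time, freq]
    fs: float
    nfft: int
    window_samples: int

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.frames)


def _nfft_for(params: DsstftParams, fs: float, win_samples: int) -> int:
    span = params.freq_range[1] - params.freq_range[0]
    df_target = span / params.freq_bins
    nfft = 1
    while fs / nfft > df_target or nfft < 4 * win_samples:
        nfft *= 2
    return nfft


def stft(
    signal: np.ndarray,
    fs: float,
    params: DsstftParams | None = None,
    t0: float = 0.0,
) -> StftFrames:
    """Hann-windowed, zero-padded STFT; frames are linearly detrended first.

    Frame centers run from ``window/2`` to ``duration - window/2`` with the
    configured hop so every frame sees a full window of data.
    """
    params = params or DsstftParams()
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    lw = int(round(params.window_length * fs))
    if lw > x.size:
        raise ValueError("window longer than the signal")
    if lw < 8:
        raise ValueError("window too short for the sampling rate")
    hop = max(1, int(round(params.hop * fs)))
    nfft = _nfft_for(params, fs, lw)
    w = get_window("hann", lw, fftbins=True)
    starts = np.arange(0, x.size - lw + 1, hop)
    frames = np.empty((starts.size, nfft // 2 + 1), dtype=complex)
    for k, s in enumerate(starts):
        seg = _detrend(x[s : s + lw], type="linear")
        frames[k] = np.fft.rfft(w * seg, n=nfft)
    times = t0 + (starts + (lw - 1) / 2.0) / fs
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return StftFrames(times, freqs, frames, fs, nfft, lw)


def short_time_cepstrum(
    frames: StftFrames, gamma: float = 0.3, threshold: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-thresholded short-time cepstrum of ``|STFT|^gamma``.

    Returns ``(quefrencies, cepstra)`` where ``cepstra[k, q]`` is the
    nonnegative cepstral energy of frame ``k`` at quefrency ``q`` seconds
    (spacing ``1/fs``).  Per frame, the soft threshold subtracts the given
    quantile of the positive-quefrency cepstrum and clips at zero, leaving
    energy only at the oscillation period and its multiples.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    mag = frames.magnitude
    if np.any(mag < 0):  # pragma: no cover - magnitudes are nonnegative
        raise ValueError("magnitudes must be nonnegative")
    cep = np.fft.irfft(mag**gamma, n=frames.nfft, axis=1)
    half = frames.nfft // 2 + 1
    cep = cep[:, :half]
    quef = np.arange(half) / frames.fs
    # Quefrencies above the window length are not observable in one frame.
    keep = quef <= frames.window_samples / frames.fs
    cep = cep[:, keep]
    quef = quef[keep]
    if quef.size > 1:
        thr = np.quantile(cep[:, 1:], threshold, axis=1, keepdims=True)
        cep = np.clip(cep - thr, 0.0, None)
        cep[:, 0] = 0.0
    return quef, cep


def deshape(
    frames: StftFrames,
    cepstral: tuple[np.ndarray, np.ndarray],
    params: DsstftParams | None = None,
) -> TFRepresentation:
    """Combine |STFT| with the inverted cepstrum into the de-shape TF map.

    ``U(t, f)`` is the thresholded cepstrum mapped onto the frequency grid at
    quefrency ``1/f`` and the output is ``W(t, f) = |STFT(t, f)| * U(t, f)``
    on the configured frequency grid, clipped at zero.  At low frequencies
    one frequency bin covers several seconds of quefrency, so ``U`` takes the
    maximum of the cepstrum over the bin's quefrency cell (a point evaluation
    would undersample the narrow cepstral peaks); where the cell is narrower
    than the quefrency spacing it falls back to linear interpolation.
    Quefrencies beyond the window length contribute nothing.
    """
    params = params or DsstftParams()
    quef, cep = cepstral
    if cep.shape[0] != frames.frames.shape[0]:
        raise ValueError("cepstral frames do not match the STFT frames")
    f_out = params.out_freqs()
    if np.any(f_out <= 0):
        raise ValueError("output frequency grid must exclude 0 Hz")
    mag = frames.magnitude
    df = f_out[1] - f_out[0] if f_out.size > 1 else f_out[0]
    # Quefrency cell [1/(f + df/2), 1/(f - df/2)] per output bin.
    q_lo = 1.0 / (f_out + df / 2.0)
    q_hi = 1.0 / np.maximum(f_out - df / 2.0, 1e-12)
    i_lo = np.searchsorted(quef, q_lo, side="left")
    i_hi = np.searchsorted(quef, q_hi, side="right")
    mag_out = np.empty((mag.shape[0], f_out.size))
    u = np.empty_like(mag_out)
    target_q = 1.0 / f_out
    for k in range(mag.shape[0]):
        mag_out[k] = np.interp(f_out, frames.freqs, mag[k])
        row = np.interp(target_q, quef, cep[k], left=0.0, right=0.0)
        for j in range(f_out.size):
            if i_hi[j] - i_lo[j] >= 1:
                row[j] = max(row[j], cep[k][i_lo[j] : i_hi[j]].max(initial=0.0))
        u[k] = row
    values = np.clip(mag_out * u, 0.0, None)
    return TFRepresentation(
        frames.times,
        f_out,
        values,
        meta={
            "window_length": frames.window_samples / frames.fs,
            "hop": params.hop,
            "gamma": params.gamma,
            "kind": "dsstft",
        },
    )


def stft_magnitude_tf(
    frames: StftFrames, params: DsstftParams | None = None
) -> TFRepresentation:
    """Plain |STFT| on the configured output grid (for comparison plots)."""
    params = params or DsstftParams()
    f_out = params.out_freqs()
    mag = frames.magnitude
    vals = np.empty((mag.shape[0], f_out.size))
    for k in range(mag.shape[0]):
        vals[k] = np.interp(f_out, frames.freqs, mag[k])
    return TFRepresentation(
        frames.times,
        f_out,
        vals,
        meta={
            "window_length": frames.window_samples / frames.fs,
            "hop": params.hop,
            "kind": "stft",
        },
    )


def dsstft(
    signal: np.ndarray,
    fs: float,
    params: DsstftParams | None = None,
    t0: float = 0.0,
) -> TFRepresentation:
    """Convenience: STFT -> cepstrum -> de-shape in one call."""
    params = params or DsstftParams()
    frames = stft(signal, fs, params, t0=t0)
    cepstral = short_time_cepstrum(
        frames, gamma=params.gamma, threshold=params.cepstral_threshold
    )
    return deshape(frames, cepstral, params)


def extract_ridge(
    tf: TFRepresentation,
    band: tuple[float, float] | None = None,
    smooth_frames: int = 5,
) -> np.ndarray:
    """Per-frame dominant frequency, median-smoothed over ``smooth_frames``.

    Frames with no energy in the band are flagged as NaN and left out of the
    smoothing.
    """
    if band is None:
        band = (tf.freqs[0], tf.freqs[-1])
    mask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if not np.any(mask):
        raise ValueError("band outside the TF frequency grid")
    sub = tf.values[:, mask]
    f_band = tf.freqs[mask]
    ridge = np.full(tf.times.size, np.nan)
    tiny = 1e-12 * max(tf.values.max(), 1e-300)
    for k in range(sub.shape[0]):
        if sub[k].max() > tiny:
            ridge[k] = f_band[int(np.argmax(sub[k]))]
    if smooth_frames > 1 and np.isfinite(ridge).any():
        import pandas as pd

        ridge = (
            pd.Series(ridge)
            .rolling(smooth_frames, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    return ridge
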
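"""Beat-to-beat pulse transit time extraction from paired ECG/PPG.

The chain mirrors standard clinical practice: the PPG is upsampled to the ECG
rate (500 Hz) by linear interpolation, R peaks are found on the ECG with a
Pan-Tompkins-style detector, the pulse arrival per beat is the instant of the
maximum first difference on the rising part of the PPG upstroke ("fastest
ascending" point), PTT = arrival - R, and the irregular beat-indexed series is
resampled onto a uniform 4 Hz grid with a natural cubic spline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core import BeatAnnotations, PTTSeries, Waveform

__all__ = [
    "upsample_ppg",
    "detect_r_peaks",
    "detect_pulse_arrival",
    "compute_ptt",
    "resample_ptt",
    "extract_ptt_series",
]

# Physiologic search window for the pulse arrival after each R peak.
W_MIN = 0.100
W_MAX = 0.700


def upsample_ppg(ppg: Waveform, target_fs: float = 500.0) -> Waveform:
    """Linearly interpolate the PPG onto a ``target_fs`` grid.

    Values at grid points shared with the input grid are unchanged; the output
    span never extends beyond the input span.
    """
    if target_fs < ppg.fs:
        raise ValueError("target_fs must be >= the input sampling rate")
    t_in = ppg.times
    n_out = int(np.floor((ppg.n - 1) * target_fs / ppg.fs)) + 1
    t_out = ppg.t0 + np.arange(n_out) / target_fs
    y = np.interp(t_out, t_in, ppg.samples)
    return Waveform(y, target_fs, label=ppg.label, t0=ppg.t0)


def detect_r_peaks(ecg: Waveform, refractory: float = 0.250) -> np.ndarray:
    """R-peak times from a lead-II-like ECG.

    Bandpass (5-25 Hz) -> squared derivative -> 150 ms moving-window
    integration -> threshold at a fraction of the upper envelope, with the
    given refractory period, then refinement to the raw-ECG local maximum.
    """
    if ecg.duration < 5.0:
        raise ValueError("need at least 5 s of ECG")
    fs = ecg.fs
    sos = butter(2, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, ecg.samples)
    energy = np.gradient(filtered) ** 2
    win = max(1, int(round(0.150 * fs)))
    det = np.convolve(energy, np.ones(win) / win, mode="same")
    top = np.percentile(det, 99)
    if top <= 0:
        warnings.warn("flat ECG: no R peaks detected", stacklevel=2)
        return np.empty(0)
    peaks, _ = find_peaks(
        det, height=0.2 * top, distance=max(1, int(round(refractory * fs)))
    )
    if peaks.size == 0:
        warnings.warn("no R peaks detected", stacklevel=2)
        return np.empty(0)
    # Refine each detection to the raw-ECG maximum within +/- 100 ms (wide
    # enough to absorb the integration lag of half-cut QRS at record edges;
    # the refractory spacing keeps neighbouring beats out of the window).
    half = int(round(0.100 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(ecg.n, p + half + 1)
        refined.append(lo + int(np.argmax(ecg.samples[lo:hi])))
    times = ecg.t0 + np.unique(refined) / fs
    # Enforce the refractory after refinement (two detections may refine to
    # nearby raw maxima).
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= refractory:
            keep.append(i)
    return times[keep]


def detect_pulse_arrival(
    ppg: Waveform,
    r_times: np.ndarray,
    w_min: float = W_MIN,
    w_max: float = W_MAX,
    smooth: bool = False,
) -> np.ndarray:
    """Pulse-arrival time per R peak: maximum first difference on the ascent.

    For each R peak the search window is ``(r + w_min, r + w_max]``, clipped
    so it cannot reach into the next beat's window; the arrival is the
    midpoint time of the steepest rising first difference (ties broken at the
    centre of the tied run).  NaN marks beats with no rising segment in the
    window or windows extending past the record end.

    With ``smooth=True`` the first difference is smoothed over 20 ms first.
    """
    r_times = np.asarray(r_times, dtype=float)
    x = ppg.samples
    d = np.diff(x)
    if smooth:
        k = max(1, int(round(0.020 * ppg.fs)))
        d = np.convolve(d, np.ones(k) / k, mode="same")
    # d[i] is the slope between samples i and i+1 -> midpoint time.
    t_mid = ppg.t0 + (np.arange(d.size) + 0.5) / ppg.fs
    t_end = ppg.t0 + (ppg.n - 1) / ppg.fs
    arrivals = np.full(r_times.shape, np.nan)
    for b, r in enumerate(r_times):
        lo = r + w_min
        hi = r + w_max
        if b + 1 < r_times.size:
            hi = min(hi, r_times[b + 1] + w_min)
        if r + w_max > t_end:
            continue  # window extends past the record end -> missing
        i0 = int(np.searchsorted(t_mid, lo, side="right"))
        i1 = int(np.searchsorted(t_mid, hi, side="right"))
        if i0 >= i1:
            continue
        seg = d[i0:i1]
        rising = seg > 0
        if not np.any(rising):
            continue
        vmax = seg[rising].max()
        # Linear upsampling leaves runs of exactly equal differences inside
        # each native sample interval; take the centre of the tied run.
        tied = np.flatnonzero(rising & np.isclose(seg, vmax, rtol=1e-9, atol=0.0))
        arrivals[b] = t_mid[i0 + int(round(tied.mean()))]
    return arrivals


def compute_ptt(
    r_times: np.ndarray,
    arrival_times: np.ndarray,
    w_min: float = W_MIN,
    w_max: float = W_MAX,
    min_beats: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Beat-indexed PTT = arrival - R for each non-missing pair.

    Pairs whose PTT falls outside ``(w_min, w_max)`` are dropped.  Returns
    ``(beat_times, ptt_beat)``; raises if fewer than ``min_beats`` survive.
    """
    r_times = np.asarray(r_times, dtype=float)
    arrival_times = np.asarray(arrival_times, dtype=float)
    if r_times.size != arrival_times.size:
        raise ValueError("paired lists required")
    ptt = arrival_times - r_times
    ok = np.isfinite(ptt) & (ptt > w_min) & (ptt < w_max)
    if ok.sum() < min_beats:
        raise ValueError(
            f"only {int(ok.sum())} valid beats; need at least {min_beats}"
        )
    return r_times[ok], ptt[ok]


def resample_ptt(
    beat_times: np.ndarray, ptt_beat: np.ndarray, rate: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline through the beat-indexed PTT, sampled at ``rate``.

    The uniform grid is anchored at the first beat time with spacing exactly
    ``1/rate`` and never extrapolates beyond the last beat time.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    ptt_beat = np.asarray(ptt_beat, dtype=float)
    if beat_times.size < 4:
        raise ValueError("need at least 4 beats for cubic-spline resampling")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("duplicate or non-increasing beat times")
    spline = CubicSpline(beat_times, ptt_beat, bc_type="natural")
    span = beat_times[-1] - beat_times[0]
    n = int(np.floor(span * rate)) + 1
    t_uniform = beat_times[0] + np.arange(n) / rate
    return t_uniform, spline(t_uniform)


def extract_ptt_series(
    ecg: Waveform,
    ppg: Waveform,
    target_fs: float = 500.0,
    rate: float = 4.0,
    smooth: bool = False,
) -> tuple[PTTSeries, BeatAnnotations]:
    """End-to-end extraction: upsample, detect, pair, resample."""
    ppg_up = upsample_ppg(ppg, target_fs) if ppg.fs < target_fs else ppg
    r_times = detect_r_peaks(ecg)
    arrivals = detect_pulse_arrival(ppg_up, r_times, smooth=smooth)
    ann = BeatAnnotations(r_times, arrivals)
    bt, ptt = compute_ptt(r_times, arrivals)
    t_u, ptt_u = resample_ptt(bt, ptt, rate=rate)
    return PTTSeries(bt, ptt, t_u, ptt_u, rate=rate), ann
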
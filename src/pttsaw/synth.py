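"""Synthetic paired ECG/PPG generator with a mechanistic dual-clock skew model.

The generator produces a lead-II-like ECG (500 Hz) and a finger-PPG-like
waveform (125 Hz) whose pulses lag each R peak by a physiologically modulated
pulse transit time (respiratory ~0.25 Hz, Mayer-wave ~0.1 Hz, optional slow
trend).  On top of the clean pair it can emulate an acquisition chain whose
PPG clock runs at a slightly different rate than the ECG clock and is
periodically corrected by a one-sample jump.  That drift-and-correction cycle
is one mechanistic hypothesis sufficient to reproduce the sawtooth pattern
seen in beat-to-beat PTT extracted from off-the-shelf patient monitors; the
actual internal behaviour of such monitors is not public, so the clock model
should be read as a phenomenological stand-in, not as reverse engineering.

A relative drift of 80 ppm corrected in 8 ms (one 125 Hz sample) quanta yields
a correction every 0.008 / 80e-6 = 100 s, i.e. a 100 s sawtooth in the
extracted PTT; presets for 75 s, 150 s and 10 s periods are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import GroundTruth, Waveform

__all__ = [
    "SimulationConfig",
    "ClockModel",
    "PRESETS",
    "preset_clock",
    "generate_beat_times",
    "synthesize_true_ptt",
    "synthesize_ecg",
    "synthesize_ppg",
    "apply_clock_skew",
    "alignment_offset",
    "ppg_pulse_template",
    "simulate_subject",
]

# QRS-like template: Gaussian spike, sigma in seconds.
_QRS_SIGMA = 0.010
_QRS_AMP = 1.0
# PPG additive noise is band-limited (monitor front ends filter the optical
# signal heavily); cutoff in Hz.
_PPG_NOISE_CUTOFF = 10.0
# PPG pulse template: raised-cosine upstroke + exponential decay.
PPG_UPSTROKE_WIDTH = 0.12
PPG_DECAY_TAU = 0.30

# Named sub-streams of the per-simulation seed, so each channel's randomness
# is reproducible independently of the others.
_STREAM_BEATS = 0
_STREAM_PTT = 1
_STREAM_ECG_NOISE = 2
_STREAM_PPG_NOISE = 3


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Parameters of one simulated subject.

    ``hrv_amplitudes`` and ``ptt_modulations`` are lists of
    ``(frequency_hz, amplitude_s)`` pairs; ``ptt_trend`` is a piecewise-linear
    additive term given as ``(time_s, value_s)`` breakpoints (added on top of
    ``ptt_baseline``; leave empty for no trend).
    """

    duration: float = 1600.0
    mean_hr: float = 75.0
    hrv_amplitudes: Sequence[tuple[float, float]] = ((0.25, 0.02), (0.1, 0.01))
    rr_jitter_sd: float = 0.005
    ptt_baseline: float = 0.25
    ptt_modulations: Sequence[tuple[float, float]] = ((0.25, 0.003), (0.095, 0.002))
    ptt_trend: Sequence[tuple[float, float]] = ()
    noise_sd_ecg: float = 0.02
    noise_sd_ppg: float = 0.005
    fs_ecg: float = 500.0
    fs_ppg: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 20.0 < self.mean_hr < 250.0:
            raise ValueError("mean_hr must lie in (20, 250) bpm")
        if not self.ptt_baseline > 0:
            raise ValueError("ptt_baseline must be positive")
        # Sampling must resolve the templates: QRS energy lives below ~40 Hz,
        # the PPG upstroke below ~1/PPG_UPSTROKE_WIDTH Hz.
        if self.fs_ecg <= 2 * 40.0:
            raise ValueError("fs_ecg too low to resolve the QRS template")
        if self.fs_ppg <= 2 * (1.0 / PPG_UPSTROKE_WIDTH):
            raise ValueError("fs_ppg too low to resolve the PPG upstroke")
        for f, a in list(self.hrv_amplitudes) + list(self.ptt_modulations):
            if a < 0:
                raise ValueError(f"modulation amplitude must be >= 0, got {a}")
            if f <= 0:
                raise ValueError(f"modulation frequency must be > 0, got {f}")
        if self.rr_jitter_sd < 0 or self.noise_sd_ecg < 0 or self.noise_sd_ppg < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class ClockModel:
    """Relative drift of the PPG clock plus its periodic correction.

    ``drift_ppm`` is the parts-per-million rate offset of the PPG timebase
    relative to the ECG timebase.  The accumulated alignment offset grows at
    ``drift_ppm * 1e-6`` s/s; whenever it reaches ``correction_trigger`` the
    chain corrects by ``correction_quantum`` seconds in one instantaneous jump
    (a dropped/held sample).  With trigger == quantum the offset is a sawtooth
    in [0, quantum) with period ``quantum / (drift_ppm * 1e-6)``.
    """

    drift_ppm: float = 80.0
    correction_quantum: float = 0.008
    correction_trigger: float | None = None
    initial_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.drift_ppm < 0:
            raise ValueError("drift_ppm must be >= 0")
        if not self.correction_quantum > 0:
            raise ValueError("correction_quantum must be positive")
        if self.correction_trigger is None:
            self.correction_trigger = self.correction_quantum
        if not self.correction_trigger > 0:
            raise ValueError("correction_trigger must be positive")

    @property
    def period(self) -> float:
        """Steady-state interval between correction events, in seconds."""
        if self.drift_ppm == 0:
            return math.inf
        return self.correction_quantum / (self.drift_ppm * 1e-6)


#: Artifact presets.  Period = quantum / (drift * 1e-6).
PRESETS: dict[str, dict] = {
    "skwhsmh": {"drift_ppm": 80.0, "correction_quantum": 0.008},  # 100 s
    "cgmh75": {"drift_ppm": 320.0 / 3.0, "correction_quantum": 0.008},  # 75 s
    "cgmh150": {"drift_ppm": 160.0 / 3.0, "correction_quantum": 0.008},  # 150 s
    "cgmh10": {"drift_ppm": 800.0, "correction_quantum": 0.008},  # 10 s
    "clean": {"drift_ppm": 0.0, "correction_quantum": 0.008},  # no artifact
}


def preset_clock(name: str) -> ClockModel:
    """Build the :class:`ClockModel` for a named artifact preset."""
    try:
        return ClockModel(**PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def generate_beat_times(config: SimulationConfig) -> np.ndarray:
    """Generate strictly increasing R-peak times over [0, duration).

    The instantaneous RR interval is ``60 / mean_hr`` plus the summed
    sinusoidal heart-rate-variability modulations plus white Gaussian jitter.
    """
    rng = _stream(config.seed, _STREAM_BEATS)
    mods = [(f, a) for f, a in config.hrv_amplitudes]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(mods))
    rr0 = 60.0 / config.mean_hr
    times: list[float] = []
    t = 0.0
    while t < config.duration:
        times.append(t)
        rr = rr0
        for (f, a), ph in zip(mods, phases):
            rr += a * math.sin(2.0 * np.pi * f * t + ph)
        if config.rr_jitter_sd > 0:
            rr += config.rr_jitter_sd * rng.standard_normal()
        if rr <= 0:
            raise ValueError(
                "realized RR interval <= 0; reduce modulation amplitudes/jitter"
            )
        t += rr
    return np.asarray(times)


def _trend(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    pts = list(config.ptt_trend)
    if not pts:
        return np.zeros_like(t)
    tt = np.asarray([p[0] for p in pts], dtype=float)
    vv = np.asarray([p[1] for p in pts], dtype=float)
    return np.interp(t, tt, vv)


def synthesize_true_ptt(beat_times: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Per-beat true PTT: baseline + sinusoidal modulations + trend.

    Modulation phases are drawn once per simulation from the seed's PTT
    sub-stream so the series is reproducible.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise ValueError("beat_times must be nonempty")
    rng = _stream(config.seed, _STREAM_PTT)
    mods = [(f, a) for f, a in config.ptt_modulations]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(mods))
    ptt = np.full(beat_times.shape, config.ptt_baseline)
    for (f, a), ph in zip(mods, phases):
        ptt += a * np.sin(2.0 * np.pi * f * beat_times + ph)
    ptt += _trend(config, beat_times)
    if np.any(ptt <= 0):
        raise ValueError("synthesized PTT must stay positive; adjust config")
    return ptt


def synthesize_ecg(beat_times: np.ndarray, config: SimulationConfig) -> Waveform:
    """Lead-II-like ECG: a QRS-shaped Gaussian spike at each beat + noise."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (
        beat_times.min() < 0 or beat_times.max() > config.duration
    ):
        raise ValueError("beat_times must lie within [0, duration]")
    fs = config.fs_ecg
    n = int(round(config.duration * fs))
    x = np.zeros(n)
    half = int(round(5 * _QRS_SIGMA * fs))
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs - tb
        x[lo:hi] += _QRS_AMP * np.exp(-0.5 * (tt / _QRS_SIGMA) ** 2)
    if config.noise_sd_ecg > 0:
        rng = _stream(config.seed, _STREAM_ECG_NOISE)
        x += config.noise_sd_ecg * rng.standard_normal(n)
    return Waveform(x, fs, label="ECG")


def ppg_pulse_template(u: np.ndarray) -> np.ndarray:
    """Closed-form PPG pulse, ``u`` = time since pulse onset (seconds).

    Raised-cosine upstroke of width ``PPG_UPSTROKE_WIDTH`` followed by an
    exponential decay with time constant ``PPG_DECAY_TAU``.  The continuous
    template's steepest ascent is exactly at ``u = PPG_UPSTROKE_WIDTH / 2``
    (where the upstroke derivative ``(pi / 2W) * sin(pi u / W)`` peaks), which
    is what the pulse-arrival detector is meant to find.
    """
    u = np.asarray(u, dtype=float)
    w = PPG_UPSTROKE_WIDTH
    out = np.zeros_like(u)
    rising = (u >= 0) & (u <= w)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / w))
    falling = u > w
    out[falling] = np.exp(-(u[falling] - w) / PPG_DECAY_TAU)
    return out


def synthesize_ppg(
    beat_times: np.ndarray, true_ptt: np.ndarray, config: SimulationConfig
) -> Waveform:
    """PPG waveform whose per-beat steepest-ascent instant is beat + PTT."""
    beat_times = np.asarray(beat_times, dtype=float)
    true_ptt = np.asarray(true_ptt, dtype=float)
    if beat_times.size != true_ptt.size:
        raise ValueError("beat_times and true_ptt lengths must match")
    arrivals = beat_times + true_ptt
    if arrivals.size >= 2:
        gaps = np.diff(arrivals)
        if np.any(PPG_UPSTROKE_WIDTH > 0.9 * gaps):
            raise ValueError(
                "PPG upstrokes overlap beyond 90% of the inter-beat interval"
            )
    fs = config.fs_ppg
    n = int(round(config.duration * fs))
    x = np.zeros(n)
    w = PPG_UPSTROKE_WIDTH
    tail = w + 6 * PPG_DECAY_TAU
    for a in arrivals:
        onset = a - w / 2.0  # steepest ascent lands exactly at the arrival
        lo = max(0, int(math.floor(onset * fs)))
        hi = min(n, int(math.ceil((onset + tail) * fs)) + 1)
        if lo >= hi:
            continue
        u = np.arange(lo, hi) / fs - onset
        x[lo:hi] += ppg_pulse_template(u)
    if config.noise_sd_ppg > 0:
        from scipy.signal import butter, sosfiltfilt

        rng = _stream(config.seed, _STREAM_PPG_NOISE)
        noise = rng.standard_normal(n)
        sos = butter(4, _PPG_NOISE_CUTOFF, btype="lowpass", fs=fs, output="sos")
        noise = sosfiltfilt(sos, noise)
        sd = noise.std()
        if sd > 0:
            noise *= config.noise_sd_ppg / sd
        x += noise
    return Waveform(x, fs, label="PPG")


def alignment_offset(clock: ClockModel, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alignment offset of the drifting clock at nominal times ``t``.

    Returns ``(offset, correction_times)``.  The offset grows linearly at
    ``drift_ppm * 1e-6`` s/s from ``initial_offset`` and drops by
    ``correction_quantum`` at each correction event (triggered whenever it
    reaches ``correction_trigger``).
    """
    t = np.asarray(t, dtype=float)
    eps = clock.drift_ppm * 1e-6
    raw = clock.initial_offset + eps * t
    if eps == 0:
        return raw, np.empty(0)
    trig = clock.correction_trigger
    q = clock.correction_quantum
    # Event j (1-based) fires when initial + eps*t == trig + (j-1)*q.
    t_end = float(t.max(initial=0.0))
    n_events = int(math.floor((clock.initial_offset + eps * t_end - trig) / q)) + 1
    n_events = max(n_events, 0)
    events = (trig + q * np.arange(n_events) - clock.initial_offset) / eps
    events = events[(events > 0) & (events <= t_end)]
    n_corr = np.searchsorted(events, t, side="right")
    return raw - q * n_corr, events


def apply_clock_skew(
    ppg: Waveform, clock: ClockModel
) -> tuple[Waveform, np.ndarray]:
    """Record ``ppg`` through the drifting, periodically corrected timebase.

    The recorded sample at nominal time ``t`` is the true signal at
    ``t + offset(t)``, obtained by linear interpolation; returns the distorted
    waveform and the correction event times.
    """
    t = ppg.times
    offset, events = alignment_offset(clock, t - ppg.t0)
    warped = np.interp(t + offset, t, ppg.samples)
    return Waveform(warped, ppg.fs, label=ppg.label, t0=ppg.t0), events


def simulate_subject(
    config: SimulationConfig, clock: ClockModel | None = None
) -> tuple[Waveform, Waveform, GroundTruth]:
    """Full simulation of one subject: ECG, (possibly skewed) PPG, truth."""
    beats = generate_beat_times(config)
    ptt = synthesize_true_ptt(beats, config)
    ecg = synthesize_ecg(beats, config)
    ppg = synthesize_ppg(beats, ptt, config)
    corrections = np.empty(0)
    if clock is not None:
        ppg, corrections = apply_clock_skew(ppg, clock)
    return ecg, ppg, GroundTruth(beats, ptt, corrections)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (convenience for cohorts)."""
    return replace(config, seed=seed)
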
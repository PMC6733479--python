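"""Core data containers shared across the pipeline.

All timestamps are in seconds, sample ``i`` of a uniformly sampled channel
lives at ``t0 + i / fs`` (0-based indexing throughout the project).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Waveform",
    "GroundTruth",
    "BeatAnnotations",
    "PTTSeries",
    "TFRepresentation",
]


@dataclass
class Waveform:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : array of amplitudes (arbitrary units)
    fs : sampling rate in Hz
    label : channel name (e.g. ``"ECG"`` or ``"PPG"``)
    t0 : time of sample 0 in seconds
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class GroundTruth:
    """Simulator ground truth: true beat times, true PTT, clock corrections."""

    beat_times: np.ndarray
    true_ptt: np.ndarray
    correction_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.true_ptt = np.asarray(self.true_ptt, dtype=float)
        self.correction_times = np.asarray(self.correction_times, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.true_ptt.size != self.beat_times.size:
            raise ValueError("true_ptt must have one value per beat")
        if np.any(self.true_ptt <= 0):
            raise ValueError("true PTT values must be positive")


@dataclass
class BeatAnnotations:
    """Per-beat R-peak times and paired PPG pulse-arrival times.

    ``arrival_times`` holds NaN where no arrival could be paired to the R peak.
    """

    r_times: np.ndarray
    arrival_times: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        if self.arrival_times.size != self.r_times.size:
            raise ValueError("one arrival slot per R peak required")
        valid = np.isfinite(self.arrival_times)
        if np.any(self.arrival_times[valid] <= self.r_times[valid]):
            raise ValueError("arrival times must follow their R peaks")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.arrival_times).sum())


@dataclass
class PTTSeries:
    """Beat-indexed PTT values plus their uniformly resampled version."""

    beat_times: np.ndarray
    ptt_beat: np.ndarray
    t_uniform: np.ndarray
    ptt_uniform: np.ndarray
    rate: float = 4.0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ptt_beat = np.asarray(self.ptt_beat, dtype=float)
        self.t_uniform = np.asarray(self.t_uniform, dtype=float)
        self.ptt_uniform = np.asarray(self.ptt_uniform, dtype=float)
        if self.ptt_beat.size != self.beat_times.size:
            raise ValueError("one PTT value per beat required")
        if self.ptt_beat.size and not np.all(
            (self.ptt_beat > 0) & (self.ptt_beat < 1.0)
        ):
            raise ValueError("beat PTT values must lie in (0, 1) s")
        if self.t_uniform.size > 1:
            dt = np.diff(self.t_uniform)
            if not np.allclose(dt, 1.0 / self.rate, rtol=0, atol=1e-9):
                raise ValueError("t_uniform must be spaced at exactly 1/rate")
        if self.t_uniform.size and self.beat_times.size:
            if (
                self.t_uniform[0] < self.beat_times[0] - 1e-9
                or self.t_uniform[-1] > self.beat_times[-1] + 1e-9
            ):
                raise ValueError("uniform grid must not extrapolate beyond beats")


@dataclass
class TFRepresentation:
    """Nonnegative time-frequency matrix on explicit grids.

    ``values`` is indexed [time, frequency]; ``meta`` records the window
    length and hop used to build it.
    """

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.times.size}, {self.freqs.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TF values must be finite")
        if np.any(self.values < 0):
            raise ValueError("TF values must be nonnegative")
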
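"""Constant-period sawtooth removal by period-synchronous template subtraction.

The series is folded modulo the detected period, the per-phase median across
cycles forms a zero-mean one-period template (incoherent physiology averages
out), and the tiled template is subtracted at the phase maximizing the
cross-correlation.  This deliberately simple, transparent scheme applies only
to the regular constant-period case; a guard compares the template RMS with a
phase-shuffled null and refuses removal when no coherent periodic component
is present, so correction can never be worse than doing nothing by much.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import detrend as _detrend

__all__ = [
    "RemovalRefused",
    "estimate_sawtooth_template",
    "estimate_phase",
    "subtract_artifact",
    "remove_sawtooth",
]


class RemovalRefused(RuntimeError):
    """Raised when no coherent periodic artifact is detectable."""


def _phase_bins(period: float, fs: float) -> int:
    return max(4, int(round(period * fs)))


def _fold_indices(n: int, fs: float, period: float, n_bins: int) -> np.ndarray:
    t = np.arange(n) / fs
    # Nearest phase bin (floor would split bins through float rounding when
    # the period is an integer number of samples).
    return (np.floor((t % period) / period * n_bins + 0.5)).astype(int) % n_bins


def estimate_sawtooth_template(
    ptt_uniform: np.ndarray, period: float, fs: float = 4.0
) -> np.ndarray:
    """One-period, zero-mean artifact template by per-phase median folding.

    The series is linearly detrended, folded modulo ``period`` into
    ``round(period * fs)`` phase bins, and the per-bin median across cycles
    is returned with its mean removed.  Requires at least 3 full periods.
    """
    x = np.asarray(ptt_uniform, dtype=float)
    if not period > 0:
        raise ValueError("period must be positive")
    if x.size / fs < 3 * period:
        raise ValueError("need at least 3 periods of data to fold")
    xd = _detrend(x, type="linear")
    n_bins = _phase_bins(period, fs)
    idx = _fold_indices(x.size, fs, period, n_bins)
    template = np.empty(n_bins)
    for b in range(n_bins):
        template[b] = np.median(xd[idx == b])
    return template - template.mean()


def _tiled(template: np.ndarray, n: int, fs: float, period: float, shift: int) -> np.ndarray:
    idx = _fold_indices(n, fs, period, template.size)
    return template[(idx + shift) % template.size]


def estimate_phase(
    ptt_uniform: np.ndarray, template: np.ndarray, period: float, fs: float = 4.0
) -> int:
    """Phase-bin shift maximizing cross-correlation with the tiled template."""
    x = _detrend(np.asarray(ptt_uniform, dtype=float), type="linear")
    idx = _fold_indices(x.size, fs, period, template.size)
    # score(s) = sum_i x_i * template[(idx_i + s) % P] computed via per-bin sums
    bin_sums = np.bincount(idx, weights=x, minlength=template.size)
    scores = [
        float(np.dot(bin_sums, np.roll(template, -s))) for s in range(template.size)
    ]
    return int(np.argmax(scores))


def subtract_artifact(
    ptt_uniform: np.ndarray,
    template: np.ndarray,
    period: float,
    phase: int | None = None,
    fs: float = 4.0,
) -> np.ndarray:
    """Subtract the tiled template at the given (or estimated) phase shift."""
    x = np.asarray(ptt_uniform, dtype=float)
    template = np.asarray(template, dtype=float)
    if phase is None:
        phase = estimate_phase(x, template, period, fs=fs)
    return x - _tiled(template, x.size, fs, period, phase)


def remove_sawtooth(
    ptt_uniform: np.ndarray,
    period: float,
    fs: float = 4.0,
    n_null: int = 20,
    null_factor: float = 1.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract the sawtooth; refuse when nothing coherent exists.

    The guard folds ``n_null`` random permutations of the *residual* (series
    minus the tiled candidate template, so the null measures only incoherent
    variance) and refuses, raising :class:`RemovalRefused`, unless the
    template RMS exceeds ``null_factor`` times the mean null template RMS.
    Returns ``(corrected, template)``.
    """
    x = np.asarray(ptt_uniform, dtype=float)
    template = estimate_sawtooth_template(x, period, fs=fs)
    corrected = subtract_artifact(x, template, period, phase=0, fs=fs)
    rng = rng or np.random.default_rng(0)
    null_rms = []
    for _ in range(n_null):
        shuffled = rng.permutation(corrected)
        null_t = estimate_sawtooth_template(shuffled, period, fs=fs)
        null_rms.append(np.sqrt(np.mean(null_t**2)))
    t_rms = np.sqrt(np.mean(template**2))
    if t_rms < null_factor * float(np.mean(null_rms)):
        raise RemovalRefused(
            f"template RMS {t_rms:.2g} below {null_factor}x the phase-shuffled "
            f"null ({np.mean(null_rms):.2g}); nothing coherent to remove"
        )
    return corrected, template
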
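"""Cohort-level aggregation of time-frequency maps.

A common, machine-borne artifact line survives averaging TF maps across
subjects, while idiosyncratic physiological content (whose timing differs
per subject) is attenuated -- which is the argument that a persistent
averaged ridge is non-physiological.  Maps are max-normalized per subject
before averaging because PTT oscillation amplitudes differ across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TFRepresentation

__all__ = ["CohortTF", "truncate_to_common", "average_tf"]


@dataclass
class CohortTF:
    """Elementwise mean of per-subject max-normalized TF maps."""

    common_times: np.ndarray
    freqs: np.ndarray
    mean_values: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.common_times = np.asarray(self.common_times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mean_values = np.asarray(self.mean_values, dtype=float)
        if self.mean_values.shape != (self.common_times.size, self.freqs.size):
            raise ValueError("mean_values shape must match the grids")
        if np.any(self.mean_values < 0) or np.any(self.mean_values > 1 + 1e-12):
            raise ValueError("mean of normalized maps must lie in [0, 1]")

    def as_tf(self) -> TFRepresentation:
        return TFRepresentation(
            self.common_times,
            self.freqs,
            self.mean_values,
            meta={"kind": "cohort_mean", "n_subjects": self.n_subjects},
        )


def _check_grids(tfs: list[TFRepresentation]) -> None:
    if len(tfs) < 2:
        raise ValueError("need at least 2 subjects")
    f0 = tfs[0].freqs
    for tf in tfs:
        if tf.times.size == 0 or tf.values.size == 0:
            raise ValueError("empty TF representation")
        if tf.freqs.size != f0.size or not np.allclose(tf.freqs, f0):
            raise ValueError("all subjects must share the frequency grid")


def truncate_to_common(tfs: list[TFRepresentation]) -> list[TFRepresentation]:
    """Truncate every subject's TF map to the shortest common time span.

    Frame times are re-referenced to each subject's own first frame so that
    recordings starting at different absolute times can be averaged; frame
    spacing (hop) must agree across subjects.
    """
    _check_grids(tfs)
    span = min(float(tf.times[-1] - tf.times[0]) for tf in tfs)
    hops = [np.diff(tf.times) for tf in tfs if tf.times.size > 1]
    if hops and not all(np.allclose(h, hops[0][0]) for h in hops):
        raise ValueError("subjects must share the frame hop")
    out = []
    for tf in tfs:
        rel = tf.times - tf.times[0]
        keep = rel <= span + 1e-9
        out.append(
            TFRepresentation(rel[keep], tf.freqs, tf.values[keep], dict(tf.meta))
        )
    return out


def average_tf(tfs: list[TFRepresentation]) -> CohortTF:
    """Elementwise mean of max-normalized maps on a common grid.

    Subjects must already share grids (use :func:`truncate_to_common` first);
    the subject time grids must agree elementwise.
    """
    _check_grids(tfs)
    n_t = tfs[0].times.size
    for tf in tfs:
        if tf.times.size != n_t or not np.allclose(tf.times, tfs[0].times):
            raise ValueError(
                "subjects must share the time grid; run truncate_to_common first"
            )
    stack = []
    for tf in tfs:
        m = tf.values.max()
        stack.append(tf.values / m if m > 0 else tf.values)
    mean = np.mean(stack, axis=0)
    return CohortTF(tfs[0].times.copy(), tfs[0].freqs.copy(), mean, len(tfs))
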
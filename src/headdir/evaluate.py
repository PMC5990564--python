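"""Accuracy and effort metrics.

Circular angle differences (against ground truth or between independent
coders) and manual-input accounting: how often a human had to intervene,
summarised per trial and as a fraction of all coded frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "circular_diff",
    "CoderSeries",
    "max_pairwise_diff",
    "ManualInputSummary",
    "manual_input_stats",
]


def circular_diff(a: float, b: float) -> float:
    """Smaller arc distance between two angles in degrees, in [0, 180]."""
    d = abs(float(a) - float(b)) % 360.0
    return min(d, 360.0 - d)


@dataclass
class CoderSeries:
    """One coder's per-frame head directions over an aligned frame index set."""

    label: str
    frame_index: np.ndarray
    hdir: np.ndarray
    mhd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index)
        self.hdir = np.asarray(self.hdir, dtype=float)
        if len(self.frame_index) != len(self.hdir):
            raise ValueError("frame_index and hdir lengths differ")


def max_pairwise_diff(series: Sequence[CoderSeries]) -> np.ndarray:
    """Per-frame maximum circular difference over all coder pairs.

    With two series this reduces to the plain circular difference; with
    three it is the inter-coder disagreement band plotted in multi-coder
    comparisons.
    """
    if len(series) < 2:
        raise ValueError("need at least two coder series")
    ref = series[0].frame_index
    for s in series[1:]:
        if len(s.frame_index) != len(ref) or not np.array_equal(s.frame_index, ref):
            raise ValueError(
                f"series {s.label!r} is not aligned with {series[0].label!r}"
            )
    n = len(ref)
    out = np.zeros(n)
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            d = np.abs(series[i].hdir - series[j].hdir) % 360.0
            d = np.minimum(d, 360.0 - d)
            out = np.maximum(out, d)
    return out


@dataclass
class ManualInputSummary:
    """Manual-effort accounting across trials."""

    total_manual: int
    total_frames: int
    per_trial: list[int] = field(repr=False)
    mean_per_trial: float = 0.0
    median_per_trial: float = 0.0
    sd_population: float = 0.0
    sd_sample: float = 0.0
    percent_of_frames: float = 0.0


def _manual_flags(records) -> np.ndarray:
    arr = np.asarray(records)
    if arr.dtype == bool or np.issubdtype(arr.dtype, np.number):
        return arr.astype(bool)
    return np.array([bool(r.m_hpos) for r in records])


def manual_input_stats(
    records, trial_boundaries: Sequence[tuple[int, int]]
) -> ManualInputSummary:
    """Count explicit manual inputs per trial and summarise coder effort.

    ``records`` is either a sequence of head records (their ``m_hpos``
    flag marks an explicit manual intervention) or a boolean array of the
    same meaning.  ``trial_boundaries`` are inclusive 0-based
    ``(start, end)`` index pairs that must partition the records exactly.
    """
    flags = _manual_flags(records)
    n = len(flags)
    bounds = sorted(trial_boundaries)
    if not bounds:
        raise ValueError("no trial boundaries given")
    covered = 0
    expected_start = 0
    for start, end in bounds:
        if start != expected_start or end < start:
            raise ValueError(
                f"trial boundaries do not partition the records at ({start}, {end})"
            )
        covered += end - start + 1
        expected_start = end + 1
    if covered != n:
        raise ValueError(
            f"trial boundaries cover {covered} records, but {n} were given"
        )
    per_trial = [int(flags[s : e + 1].sum()) for s, e in bounds]
    counts = np.array(per_trial, dtype=float)
    total = int(counts.sum())
    return ManualInputSummary(
        total_manual=total,
        total_frames=n,
        per_trial=per_trial,
        mean_per_trial=float(counts.mean()),
        median_per_trial=float(np.median(counts)),
        sd_population=float(counts.std(ddof=0)),
        sd_sample=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        percent_of_frames=100.0 * total / n if n else 0.0,
    )
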
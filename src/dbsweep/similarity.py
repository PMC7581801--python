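"""Euclidean-distance similarity between condition-averaged rotation traces.

Each condition is summarized by a fixed-length trace: every animal's ON
window is re-zeroed at onset, linearly resampled onto a uniform grid
(default 30 points over the 30-s window, i.e. 1 Hz), converted to the
requested units, then averaged pointwise across animals. Distances between
two such traces are plain Euclidean norms, so a matrix of them is symmetric,
zero on the diagonal and satisfies the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AngularTrajectory
from .errors import DomainError
from .protocols import SessionProtocol, episode_windows

__all__ = [
    "ConditionTrace",
    "SimilarityMatrix",
    "condition_trace",
    "euclidean_distance",
    "ed_matrix",
]

UNITS = ("rotations", "degrees")


@dataclass(frozen=True)
class ConditionTrace:
    """Cohort-mean re-zeroed rotation trace for one condition."""

    label: str
    values: np.ndarray = field(repr=False)
    units: str = "rotations"

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise DomainError(f"units must be one of {UNITS}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray = field(repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _window_for_label(protocol: SessionProtocol, label: str) -> tuple[float, float]:
    for lab, start, end, _train in episode_windows(protocol):
        if lab == label:
            return start, end
    raise KeyError(f"condition {label!r} not found in protocol")


def condition_trace(
    items: Sequence[tuple[AngularTrajectory, SessionProtocol]],
    label: str,
    grid_n: int = 30,
    units: str = "rotations",
) -> ConditionTrace:
    """Average re-zeroed, resampled window traces across animals.

    ``items`` pairs each animal's trajectory with its (possibly
    individualized) protocol; windows are located by condition label, so
    protocols must share episode timing and labels.
    """
    if not items:
        raise KeyError("no trajectories supplied")
    if grid_n < 2:
        raise DomainError("grid_n must be >= 2")
    if units not in UNITS:
        raise DomainError(f"units must be one of {UNITS}")
    acc = np.zeros(grid_n)
    for traj, protocol in items:
        start, end = _window_for_label(protocol, label)
        t = traj.time_s
        mask = (t >= start) & (t < end)
        idx = np.nonzero(mask)[0]
        if idx.size < 2:
            raise DomainError(f"window for {label!r} holds fewer than 2 samples")
        angle = np.asarray(traj.angle_deg, dtype=float)[idx]
        rezeroed = angle - angle[0]
        grid = np.linspace(start, end, grid_n)
        resampled = np.interp(grid, t[idx], rezeroed)
        acc += resampled
    mean_deg = acc / len(items)
    values = mean_deg / 360.0 if units == "rotations" else mean_deg
    return ConditionTrace(label=label, values=values, units=units)


def euclidean_distance(a: ConditionTrace, b: ConditionTrace) -> float:
    """``sqrt(sum_i (a_i - b_i)^2)`` between two equal-grid traces."""
    if a.values.shape != b.values.shape:
        raise DomainError("traces differ in grid length")
    if a.units != b.units:
        raise DomainError("traces differ in units")
    return float(np.sqrt(np.sum((a.values - b.values) ** 2)))


def ed_matrix(traces: Sequence[ConditionTrace]) -> SimilarityMatrix:
    """All pairwise Euclidean distances; symmetric with a zero diagonal."""
    if len(traces) < 2:
        raise DomainError("need at least 2 traces")
    n = len(traces)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = euclidean_distance(traces[i], traces[j])
            values[i, j] = values[j, i] = d
    return SimilarityMatrix(labels=[tr.label for tr in traces], values=values)
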
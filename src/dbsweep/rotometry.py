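"""Per-episode behavioral features from angular trajectories.

Features are computed on half-open windows ``[start, end)`` after re-zeroing
the cumulative angle at the first in-window sample, so they are invariant to
constant angular offsets. ``max_rotation`` is the headline feature; the
signed window-end value is kept as ``net_rotation``. AUC is the trapezoidal
integral of the rotation count over the window (units: rotation·s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AngularTrajectory
from .errors import CoverageError, DomainError
from .protocols import SessionProtocol, episode_windows
from .waveforms import charge_rate

__all__ = ["EpisodeFeatures", "episode_features", "session_features", "assess_lesion"]

FEATURE_COLUMNS = [
    "animal",
    "episode_label",
    "max_rotation",
    "net_rotation",
    "auc_rot_s",
    "distance_cm",
    "charge_rate_uCs",
]


@dataclass(frozen=True)
class EpisodeFeatures:
    label: str
    max_rotation: float
    net_rotation: float
    auc: float
    distance: float | None  # cm; None when the trajectory has no position


def episode_features(
    traj: AngularTrajectory, window: tuple[float, float], label: str = ""
) -> EpisodeFeatures:
    """Extract features for one ``[start, end)`` window of a trajectory."""
    start, end = window
    if not end > start:
        raise DomainError("window must have positive length")
    t = traj.time_s
    mask = (t >= start) & (t < end)
    idx = np.nonzero(mask)[0]
    if idx.size < 2:
        raise DomainError(
            f"window [{start}, {end}) holds {idx.size} samples; need at least 2"
        )
    angle = np.asarray(traj.angle_deg, dtype=float)[idx]
    rot = (angle - angle[0]) / 360.0
    tw = t[idx]
    auc = float(np.trapezoid(rot, tw))
    distance = None
    if traj.has_position:
        dx = np.diff(np.asarray(traj.x_cm, dtype=float)[idx])
        dy = np.diff(np.asarray(traj.y_cm, dtype=float)[idx])
        distance = float(np.sum(np.hypot(dx, dy)))
    return EpisodeFeatures(
        label=label,
        max_rotation=float(np.max(rot)),
        net_rotation=float(rot[-1]),
        auc=auc,
        distance=distance,
    )


def session_features(
    traj: AngularTrajectory, protocol: SessionProtocol
) -> pd.DataFrame:
    """One feature row per ON episode, in protocol order.

    Adds the per-episode injected charge rate (μC/s) for joint reporting.
    """
    windows = episode_windows(protocol)
    missing = [
        label for label, _, end, _ in windows if end > traj.duration_s + traj.dt_s / 2
    ]
    if missing:
        raise CoverageError(
            "trajectory shorter than protocol; uncovered windows: " + ", ".join(missing)
        )
    rows = []
    animal = traj.meta.get("animal_id", "")
    for label, start, end, train in windows:
        f = episode_features(traj, (start, end), label)
        rows.append(
            {
                "animal": animal,
                "episode_label": label,
                "max_rotation": f.max_rotation,
                "net_rotation": f.net_rotation,
                "auc_rot_s": f.auc,
                "distance_cm": np.nan if f.distance is None else f.distance,
                "charge_rate_uCs": charge_rate(train),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def assess_lesion(
    traj: AngularTrajectory, duration_min: float = 30.0, threshold_rpm: float = 3.0
) -> bool:
    """Lesion-success criterion: net contralateral rotation rate >= threshold.

    True iff the net (signed) rotation count over ``duration_min`` divided by
    the duration is at least ``threshold_rpm`` rotations per minute;
    ipsiversive (negative) rotation never qualifies.
    """
    n_end = int(round(duration_min * 60.0 / traj.dt_s))
    if traj.n_samples <= n_end:
        raise DomainError(
            f"trajectory covers {traj.duration_s:.1f} s; "
            f"need {duration_min * 60:.0f} s for lesion assessment"
        )
    angle = np.asarray(traj.angle_deg, dtype=float)
    net_rot = (angle[n_end] - angle[0]) / 360.0
    return bool(net_rot / duration_min >= threshold_rpm)
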
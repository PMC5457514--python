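"""Visual-cliff behaviour metrics from tracked 2-D trajectories.

The arena is a rectangle split into a shallow and an apparently deep half;
depth perception shows up as a preference for the shallow side. Metrics are
time-weighted side occupancy, centre-zone time (an anxiety control),
total path length and mean locomotion velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ArenaGeometry", "CliffMetrics", "zone_occupancy", "locomotion_metrics", "cliff_metrics"]

TRIAL_DURATION_S = 300.0  # trials end after 5 min


@dataclass(frozen=True)
class ArenaGeometry:
    """Rectangular cliff arena split into two equal plates along x.

    Defaults: 50 × 36 cm arena divided into two 25 × 36 cm halves, shallow
    half at x < ``shallow_max_x``. The centre zone is a concentric rectangle
    with ``centre_fraction`` of each linear dimension (default half, i.e.
    25% of the area); the arena's own geometry leaves its exact extent a
    free analysis choice.
    """

    width_cm: float = 50.0
    height_cm: float = 36.0
    centre_fraction: float = 0.5

    @property
    def shallow_max_x(self) -> float:
        return self.width_cm / 2.0

    def in_shallow(self, x, y=None):
        """Boundary points count as shallow (documented tie rule)."""
        return np.asarray(x) <= self.shallow_max_x

    def in_centre(self, x, y):
        hw = self.width_cm * self.centre_fraction / 2.0
        hh = self.height_cm * self.centre_fraction / 2.0
        cx, cy = self.width_cm / 2.0, self.height_cm / 2.0
        return (np.abs(np.asarray(x) - cx) <= hw) & (np.abs(np.asarray(y) - cy) <= hh)


@dataclass
class CliffMetrics:
    pct_time_shallow: float
    pct_time_deep: float
    pct_time_centre: float
    total_distance_cm: float
    mean_velocity_cm_s: float


def _prepare(traj: pd.DataFrame, arena: ArenaGeometry, truncate_s: float | None):
    t = traj["t_s"].to_numpy(dtype=float)
    x = traj["x_cm"].to_numpy(dtype=float)
    y = traj["y_cm"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trajectory needs at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if truncate_s is not None:
        keep = t - t[0] <= truncate_s
        t, x, y = t[keep], x[keep], y[keep]
        if t.size < 2:
            raise ValueError("trajectory needs at least 2 samples after truncation")
    oob = (x < 0) | (x > arena.width_cm) | (y < 0) | (y > arena.height_cm)
    if oob.any():
        warnings.warn(f"{oob.sum()} out-of-bounds samples clipped to arena walls")
        x = np.clip(x, 0.0, arena.width_cm)
        y = np.clip(y, 0.0, arena.height_cm)
    return t, x, y


def zone_occupancy(
    traj: pd.DataFrame,
    arena: ArenaGeometry | None = None,
    truncate_s: float | None = TRIAL_DURATION_S,
) -> dict:
    """Time-weighted percentage of trial time per zone.

    Each inter-sample interval is assigned to the zone of its earlier
    sample; points exactly on the dividing line count as shallow. Shallow
    and deep percentages sum to 100; the centre zone overlaps both.
    """
    arena = arena or ArenaGeometry()
    t, x, y = _prepare(traj, arena, truncate_s)
    dt = np.diff(t)
    total = dt.sum()
    shallow = dt[arena.in_shallow(x[:-1])].sum()
    centre = dt[arena.in_centre(x[:-1], y[:-1])].sum()
    return {
        "pct_time_shallow": 100.0 * shallow / total,
        "pct_time_deep": 100.0 * (total - shallow) / total,
        "pct_time_centre": 100.0 * centre / total,
    }


def locomotion_metrics(
    traj: pd.DataFrame,
    arena: ArenaGeometry | None = None,
    truncate_s: float | None = TRIAL_DURATION_S,
) -> dict:
    """Total path length (cm) and mean velocity (cm/s)."""
    arena = arena or ArenaGeometry()
    t, x, y = _prepare(traj, arena, truncate_s)
    steps = np.hypot(np.diff(x), np.diff(y))
    dist = float(steps.sum())
    elapsed = float(t[-1] - t[0])
    return {"total_distance_cm": dist, "mean_velocity_cm_s": dist / elapsed}


def cliff_metrics(
    traj: pd.DataFrame,
    arena: ArenaGeometry | None = None,
    truncate_s: float | None = TRIAL_DURATION_S,
) -> CliffMetrics:
    """All visual-cliff metrics for one trial."""
    occ = zone_occupancy(traj, arena, truncate_s)
    loco = locomotion_metrics(traj, arena, truncate_s)
    return CliffMetrics(
        pct_time_shallow=occ["pct_time_shallow"],
        pct_time_deep=occ["pct_time_deep"],
        pct_time_centre=occ["pct_time_centre"],
        total_distance_cm=loco["total_distance_cm"],
        mean_velocity_cm_s=loco["mean_velocity_cm_s"],
    )
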
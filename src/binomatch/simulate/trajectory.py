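"""Biased random-walk trajectories in a rectangular visual-cliff arena."""

from __future__ import annotations

import numpy as np
import pandas as pd

from binomatch.behavior import ArenaGeometry

__all__ = ["simulate_trajectory"]


def simulate_trajectory(
    arena: ArenaGeometry | None = None,
    side_bias: float = 0.5,
    duration_s: float = 300.0,
    step_hz: float = 10.0,
    seed: int | None = None,
    *,
    step_cm: float = 0.5,
    start_xy: tuple | None = None,
) -> pd.DataFrame:
    """Random walk with a controllable bias toward the shallow side.

    At every step a uniformly random heading is drawn; with probability
    ``side_bias`` the x-component is pointed toward the shallow half, with
    probability 1−``side_bias`` toward the deep half. ``side_bias=0.5``
    gives an unbiased walk; ``side_bias=1`` drives the animal to the shallow
    side and keeps it there. Positions are clipped to the arena walls.

    Returns a DataFrame with columns t_s, x_cm, y_cm sampled at
    ``step_hz``.
    """
    if not 0.0 <= side_bias <= 1.0:
        raise ValueError("side_bias must be in [0, 1]")
    if duration_s <= 0 or step_hz <= 0:
        raise ValueError("duration_s and step_hz must be > 0")
    rng = np.random.default_rng(seed)
    arena = arena or ArenaGeometry()
    n = int(round(duration_s * step_hz)) + 1
    x = np.empty(n)
    y = np.empty(n)
    if start_xy is None:
        # trials start on the shallow side
        x[0], y[0] = arena.shallow_max_x / 2.0, arena.height_cm / 2.0
    else:
        x[0], y[0] = start_xy
    headings = rng.uniform(0.0, 2 * np.pi, n - 1)
    toward_shallow = rng.random(n - 1) < side_bias
    dx = step_cm * np.cos(headings)
    dy = step_cm * np.sin(headings)
    # shallow half occupies x < shallow_max_x
    for i in range(1, n):
        step_x = dx[i - 1]
        # direct the x-component toward the chosen half's centre
        if toward_shallow[i - 1]:
            target = arena.shallow_max_x / 2.0
        else:
            target = (arena.shallow_max_x + arena.width_cm) / 2.0
        step_x = np.abs(step_x) * np.sign(target - x[i - 1]) if target != x[i - 1] else step_x
        x[i] = np.clip(x[i - 1] + step_x, 0.0, arena.width_cm)
        y[i] = np.clip(y[i - 1] + dy[i - 1], 0.0, arena.height_cm)
    t = np.arange(n) / step_hz
    return pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y})
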
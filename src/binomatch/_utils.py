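"""Small shared helpers: angular arithmetic and validation."""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_direction",
    "wrap_orientation",
    "circ_dist_deg",
    "orientation_diff_deg",
]


def wrap_direction(angle_deg):
    """Wrap a direction angle into [0, 360)."""
    return np.asarray(angle_deg) % 360.0


def wrap_orientation(angle_deg):
    """Wrap an orientation angle into [0, 180)."""
    return np.asarray(angle_deg) % 180.0


def circ_dist_deg(a_deg, b_deg, period: float = 360.0):
    """Signed minimal angular difference a−b on a circle of given period.

    Result lies in [−period/2, period/2).
    """
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % period
    return np.where(d >= period / 2.0, d - period, d)


def orientation_diff_deg(a_deg, b_deg):
    """Unsigned orientation difference on the 180° cycle, in [0, 90]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)
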
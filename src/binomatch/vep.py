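"""Visual evoked potential metrics: P1 amplitude/latency, C/I ratio, acuity.

The P1 component is the first major positive deflection after a pattern
reversal; its peak-to-baseline amplitude indexes response strength. Ocular
dominance at the population level is the ratio of contralateral to
ipsilateral P1 amplitude, and visual acuity is estimated by extrapolating
the linear decline of amplitude with log spatial frequency to zero
amplitude, after subtracting the amplitude at the highest (baseline,
0.96 c/deg) spatial frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["P1Result", "p1_metrics", "ci_ratio", "visual_acuity"]

P1_WINDOW_MS = (50.0, 150.0)  # typical mouse VEP latency range


@dataclass
class P1Result:
    amplitude_uv: float
    latency_ms: float
    defined: bool


def p1_metrics(
    t_ms,
    uv,
    search_window_ms: tuple = P1_WINDOW_MS,
) -> P1Result:
    """P1 peak-to-baseline amplitude and latency from an averaged trace.

    Baseline is the mean voltage before the reversal (t < 0); the P1 peak
    is the maximum baseline-corrected deflection within the search window.
    A trace with no positive deflection in the window returns amplitude 0
    with ``defined=False``.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(uv, dtype=float)
    lo, hi = search_window_ms
    if lo < t.min() or hi > t.max():
        raise ValueError("search window extends beyond the trace")
    pre = v[t < 0]
    baseline = pre.mean() if pre.size else 0.0
    win = (t >= lo) & (t <= hi)
    seg = v[win] - baseline
    if seg.max() <= 0:
        return P1Result(0.0, np.nan, False)
    i = int(np.argmax(seg))
    return P1Result(float(seg[i]), float(t[win][i]), True)


def ci_ratio(amp_contra: float, amp_ipsi: float) -> float:
    """Contralateral/ipsilateral VEP amplitude ratio (OD plasticity index)."""
    if amp_ipsi <= 0:
        raise ValueError("ipsilateral amplitude must be > 0")
    return float(amp_contra) / float(amp_ipsi)


def visual_acuity(
    sf_cpd,
    amplitude_uv,
    *,
    baseline_sf_cpd: float | None = None,
    points: str = "descending",
) -> float:
    """Visual acuity (c/deg) by linear extrapolation to zero amplitude.

    The amplitude at the baseline (highest tested) spatial frequency is
    subtracted from all points, corrected amplitude is regressed on
    log10(SF), and acuity is the SF where the regression crosses zero.
    ``points="descending"`` (default) restricts the fit to the descending
    limb — SFs at and above the argmax of corrected amplitude — so a
    low-SF roll-off cannot bias the slope; ``points="all"`` uses every SF
    below the baseline.

    Raises when the fitted slope is not negative (no acuity limit
    detectable).
    """
    sfs = np.asarray(sf_cpd, dtype=float)
    amps = np.asarray(amplitude_uv, dtype=float)
    if sfs.size != amps.size or sfs.size < 4:
        raise ValueError("need amplitudes at >= 4 spatial frequencies")
    order = np.argsort(sfs)
    sfs, amps = sfs[order], amps[order]
    base_sf = baseline_sf_cpd if baseline_sf_cpd is not None else sfs[-1]
    i_base = int(np.argmin(np.abs(sfs - base_sf)))
    corrected = amps - amps[i_base]
    keep = np.arange(sfs.size) != i_base
    if keep.sum() < 3:
        raise ValueError("need >= 3 spatial frequencies below the baseline SF")
    sfs_k, amp_k = sfs[keep], corrected[keep]
    if points == "descending":
        i_max = int(np.argmax(amp_k))
        sfs_k, amp_k = sfs_k[i_max:], amp_k[i_max:]
    elif points != "all":
        raise ValueError(f"unknown points mode: {points!r}")
    if sfs_k.size < 2:
        raise ValueError("too few points on the descending limb")
    res = stats.linregress(np.log10(sfs_k), amp_k)
    if res.slope >= 0:
        raise ValueError("no acuity limit detectable (non-negative slope)")
    x0 = -res.intercept / res.slope
    return float(10.0**x0)


def vep_metrics_table(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Session-level VEP metrics from a per-eye amplitude-by-SF table.

    Expects columns eye, sf_cpd, p1_uv. Returns one row with the C/I ratio
    at the lowest SF and per-eye acuity estimates.
    """
    rows = {}
    low_sf = amplitudes["sf_cpd"].min()
    at_low = amplitudes[amplitudes["sf_cpd"] == low_sf].set_index("eye")["p1_uv"]
    rows["ci_ratio"] = ci_ratio(at_low["contra"], at_low["ipsi"])
    for eye, g in amplitudes.groupby("eye"):
        g = g.sort_values("sf_cpd")
        try:
            rows[f"acuity_{eye}_cpd"] = visual_acuity(g["sf_cpd"], g["p1_uv"])
        except ValueError:
            rows[f"acuity_{eye}_cpd"] = np.nan
    return pd.DataFrame([rows])
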
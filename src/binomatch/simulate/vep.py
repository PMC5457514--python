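"""Simulate visual evoked potential (VEP) sessions.

VEP amplitude declines roughly linearly with log spatial frequency up to the
acuity limit, so the generator draws per-eye P1 amplitudes from
``max(0, intercept + slope·log10(SF)) + noise`` and, optionally, raw
reversal-locked traces carrying an embedded P1 deflection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_vep_session"]

DEFAULT_SFS = (0.03, 0.06, 0.12, 0.24, 0.48, 0.96)  # 6 log steps, c/deg


def simulate_vep_session(
    slope: float,
    intercept_log_sf: float,
    ci_ratio_true: float = 2.0,
    noise_sd: float = 0.0,
    protocol_sfs=DEFAULT_SFS,
    n_sweeps: int = 1,
    seed: int | None = None,
    *,
    with_traces: bool = False,
    p1_latency_ms: float = 80.0,
    trace_duration_ms: float = 300.0,
    trace_baseline_ms: float = 50.0,
    sampling_rate_hz: float = 1000.0,
):
    """Simulate per-eye P1 amplitudes across spatial frequencies.

    Parameters
    ----------
    slope
        Amplitude change (µV) per decade of spatial frequency; must be
        negative for a valid acuity curve.
    intercept_log_sf
        Amplitude (µV) at SF = 1 c/deg on the noise-free line.
    ci_ratio_true
        True contralateral/ipsilateral amplitude ratio; ipsilateral clean
        amplitudes are the contralateral ones divided by this.
    noise_sd
        SD of additive Gaussian amplitude noise per (eye, SF, sweep).
    protocol_sfs
        Spatial frequencies tested (default: 6 log steps 0.03–0.96 c/deg).
    n_sweeps
        Independent sweeps per condition; amplitudes are averaged.
    with_traces
        Also return raw traces with a Gaussian P1 deflection of the drawn
        amplitude at ``p1_latency_ms``, preceded by ``trace_baseline_ms`` of
        pre-reversal baseline.

    Returns
    -------
    amplitudes : pandas.DataFrame
        Columns eye, sf_cpd, p1_uv.
    traces : pandas.DataFrame, optional
        Columns eye, sf_cpd, t_ms, uv (only if ``with_traces``).
    """
    if slope >= 0:
        raise ValueError("slope must be negative for a valid acuity curve")
    if ci_ratio_true <= 0:
        raise ValueError("ci_ratio_true must be > 0")
    rng = np.random.default_rng(seed)
    sfs = np.asarray(protocol_sfs, dtype=float)
    clean_contra = np.maximum(0.0, intercept_log_sf + slope * np.log10(sfs))
    rows = []
    for eye, clean in (("contra", clean_contra), ("ipsi", clean_contra / ci_ratio_true)):
        sweeps = clean[None, :] + rng.normal(0.0, noise_sd, (n_sweeps, sfs.size))
        amp = sweeps.mean(axis=0)
        for sf, a in zip(sfs, amp):
            rows.append((eye, sf, a))
    amplitudes = pd.DataFrame(rows, columns=["eye", "sf_cpd", "p1_uv"])
    if not with_traces:
        return amplitudes

    dt_ms = 1e3 / sampling_rate_hz
    t_ms = np.arange(-trace_baseline_ms, trace_duration_ms, dt_ms)
    trace_rows = []
    for _, row in amplitudes.iterrows():
        bump = row.p1_uv * np.exp(-0.5 * ((t_ms - p1_latency_ms) / 12.0) ** 2)
        uv = bump + rng.normal(0.0, noise_sd * 0.1, t_ms.size)
        trace_rows.append(
            pd.DataFrame(
                {"eye": row.eye, "sf_cpd": row.sf_cpd, "t_ms": t_ms, "uv": uv}
            )
        )
    traces = pd.concat(trace_rows, ignore_index=True)
    return amplitudes, traces
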
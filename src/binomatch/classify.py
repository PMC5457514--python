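"""Simple/complex and narrow/broad spiking classification.

Response linearity: the preferred-condition response is binned into a
100 ms post-stimulus time histogram, the spontaneous rate subtracted, and
the discrete Fourier transform taken. F1/F0 — the first-harmonic amplitude
at the grating drift frequency over the mean elevation — separates simple
(modulated, F1/F0 > 1) from complex (unmodulated) cells.

Spike width: three features of the mean extracellular waveform (positive
peak height relative to the initial trough, trough-to-peak time, and the
slope 0.5 ms after the trough) are clustered into two groups by both
k-means and average-linkage hierarchical clustering; narrow-spiking
(putative inhibitory) units are the cluster with the shorter trough-to-peak
time, and an agreement flag records whether the two algorithms produced the
identical partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from binomatch.protocol import StimulusProtocol

__all__ = [
    "Psth",
    "WaveformFeatures",
    "compute_psth",
    "f1f0",
    "classify_simple_complex",
    "waveform_features",
    "classify_spike_width",
]

PSTH_BINWIDTH_S = 0.1
F1F0_SIMPLE_THRESHOLD = 1.0  # field convention; configurable


@dataclass
class Psth:
    unit_id: object
    bin_edges_s: np.ndarray
    rate_hz: np.ndarray          # baseline-subtracted, averaged over repeats
    spont_rate_hz: float
    n_trials: int


@dataclass
class WaveformFeatures:
    unit_id: object
    peak_trough_ratio: float
    trough_to_peak_ms: float
    slope_after_trough: float    # per-ms slope, trough-normalized units
    valid: bool = True


def compute_psth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    unit_id,
    preferred_condition: dict,
    binwidth_s: float = PSTH_BINWIDTH_S,
    spont_rate_hz: float = 0.0,
) -> Psth:
    """PSTH of one unit at its preferred condition.

    ``preferred_condition`` needs keys eye, orientation_deg, sf_cpd. Counts
    are averaged across the condition's repeats, converted to Hz and the
    spontaneous rate subtracted. A trailing partial bin (duration not a
    multiple of the bin width) is dropped with a warning.
    """
    sel = (
        (~trials["is_blank"])
        & (trials["eye"] == preferred_condition["eye"])
        & (trials["orientation_deg"] == preferred_condition["orientation_deg"])
        & (trials["sf_cpd"] == preferred_condition["sf_cpd"])
    )
    cond_trials = trials[sel]
    if cond_trials.empty:
        raise ValueError("preferred condition has no trials")
    duration = float(cond_trials["duration_s"].iloc[0])
    n_bins_exact = duration / binwidth_s
    n_bins = int(np.floor(n_bins_exact + 1e-9))
    if not np.isclose(n_bins_exact, n_bins):
        warnings.warn("duration not a multiple of binwidth; dropping partial bin")
    edges = np.arange(n_bins + 1) * binwidth_s
    mine = spikes[
        (spikes["unit_id"] == unit_id)
        & spikes["trial_id"].isin(cond_trials["trial_id"])
    ]
    counts, _ = np.histogram(mine["t_rel_s"].to_numpy(), bins=edges)
    n_trials = len(cond_trials)
    rate = counts / (n_trials * binwidth_s) - spont_rate_hz
    return Psth(unit_id, edges, rate, spont_rate_hz, n_trials)


def f1f0(psth: Psth | np.ndarray, temporal_frequency_hz: float, duration_s: float | None = None):
    """First-harmonic to mean-response ratio of a PSTH.

    F0 is the PSTH mean; F1 the one-sided DFT amplitude 2|X_k|/N at the
    harmonic nearest ``temporal_frequency_hz × duration`` cycles per
    presentation (k = 3 for 2 Hz × 1.5 s), so a pure cosine of amplitude a
    on mean m gives a/m. Returns ``(ratio, defined)``; undefined (and the
    unit excluded from simple/complex analysis) when the mean response is
    not positive.
    """
    if isinstance(psth, Psth):
        rate = np.asarray(psth.rate_hz, dtype=float)
        duration_s = float(psth.bin_edges_s[-1] - psth.bin_edges_s[0])
    else:
        rate = np.asarray(psth, dtype=float)
        if duration_s is None:
            raise ValueError("duration_s required for a bare rate array")
    n = rate.size
    f0 = rate.mean()
    if f0 <= 0:
        return np.nan, False
    k = int(round(temporal_frequency_hz * duration_s))
    if not 1 <= k <= n // 2:
        raise ValueError("drift harmonic outside the resolvable DFT range")
    spec = np.fft.rfft(rate)
    f1 = 2.0 * np.abs(spec[k]) / n
    return float(f1 / f0), True


def classify_simple_complex(ratio: float, threshold: float = F1F0_SIMPLE_THRESHOLD) -> str:
    """Simple iff F1/F0 exceeds the threshold (default 1.0)."""
    if not np.isfinite(ratio):
        raise ValueError("undefined F1/F0 ratio")
    return "simple" if ratio > threshold else "complex"


def waveform_features(waveform, sampling_rate_hz: float, unit_id=None) -> WaveformFeatures:
    """Shape features of a mean spike waveform.

    The waveform is aligned to its global minimum (the initial trough) and
    normalized by trough depth, then measured: positive peak height after
    the trough relative to trough depth, trough-to-peak time in ms, and the
    local slope 0.5 ms after the trough (central difference, per ms).
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 5 or not np.all(np.isfinite(w)):
        raise ValueError("waveform too short or non-finite")
    i_trough = int(np.argmin(w))
    depth = -w[i_trough]
    if depth <= 0:
        raise ValueError("waveform has no negative trough")
    w = w / depth  # trough is −1 after normalization
    after = w[i_trough + 1 :]
    if after.size == 0 or after.max() <= 0:
        return WaveformFeatures(unit_id, np.nan, np.nan, np.nan, valid=False)
    i_peak = i_trough + 1 + int(np.argmax(after))
    dt_ms = 1e3 / sampling_rate_hz
    ttp_ms = (i_peak - i_trough) * dt_ms
    i_slope = i_trough + int(round(0.5 / dt_ms))
    if 1 <= i_slope < w.size - 1:
        slope = (w[i_slope + 1] - w[i_slope - 1]) / (2.0 * dt_ms)
    else:
        slope = np.nan
    return WaveformFeatures(
        unit_id=unit_id,
        peak_trough_ratio=float(w[i_peak]),
        trough_to_peak_ms=float(ttp_ms),
        slope_after_trough=float(slope),
    )


def classify_spike_width(features: pd.DataFrame, seed: int = 0):
    """Partition units into narrow/broad spiking by waveform shape.

    ``features`` needs columns peak_trough_ratio, trough_to_peak_ms,
    slope_after_trough (one row per unit). Features are standardized, then
    clustered by 2-means (10 restarts, seeded) and by average-linkage
    hierarchical clustering cut at two clusters. Narrow is the cluster with
    the smaller mean trough-to-peak time.

    Returns ``(labels, agreement)``: a pandas Series of {"narrow","broad"}
    indexed like ``features``, and a flag that is True when both algorithms
    produced the identical partition.
    """
    cols = ["peak_trough_ratio", "trough_to_peak_ms", "slope_after_trough"]
    X = features[cols].to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 units to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite waveform features")
    sd = X.std(axis=0)
    scale = np.maximum(1.0, np.abs(X).max(axis=0))
    if np.all(sd <= 1e-9 * scale):
        raise ValueError("all waveform features identical; no clusters")
    Xs = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Xs)
    km_labels = km.labels_
    if len(set(km_labels)) < 2:
        raise ValueError("features collapse to a single cluster")
    hc_labels = fcluster(linkage(Xs, method="average"), t=2, criterion="maxclust") - 1

    def orient(labels):
        ttp = features["trough_to_peak_ms"].to_numpy(dtype=float)
        mean0 = ttp[labels == 0].mean()
        mean1 = ttp[labels == 1].mean()
        narrow = 0 if mean0 < mean1 else 1
        return np.where(labels == narrow, "narrow", "broad")

    km_named = orient(km_labels)
    hc_named = orient(hc_labels)
    agreement = bool(np.all(km_named == hc_named))
    return pd.Series(km_named, index=features.index, name="spike_class"), agreement


def classify_units(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    protocol: StimulusProtocol,
    unit_metrics: pd.DataFrame,
    waveforms: pd.DataFrame,
    sampling_rate_hz: float,
    *,
    f1f0_threshold: float = F1F0_SIMPLE_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit F1/F0, simple/complex label and narrow/broad label.

    ``unit_metrics`` supplies each unit's dominant eye and preferred
    condition (output of :func:`binomatch.tuning.analyze_units`).
    Returns the unit_classes table.
    """
    rows = []
    for _, um in unit_metrics.iterrows():
        eye = um["dominant_eye"]
        cond = {
            "eye": eye,
            "orientation_deg": _nearest(
                protocol.orientations_deg, um[f"{eye}_pref_dir_deg"]
            ),
            "sf_cpd": um[f"{eye}_pref_sf_cpd"],
        }
        psth = compute_psth(
            spikes, trials, um["unit_id"], cond, spont_rate_hz=um["spont_rate_hz"]
        )
        ratio, defined = f1f0(psth, protocol.temporal_frequency_hz)
        rows.append(
            {
                "unit_id": um["unit_id"],
                "f1f0": ratio,
                "sc_label": classify_simple_complex(ratio, f1f0_threshold)
                if defined
                else "undefined",
            }
        )
    classes = pd.DataFrame(rows)

    feats = []
    for uid, g in waveforms.groupby("unit_id"):
        w = g.sort_values("sample_idx")["amplitude"].to_numpy()
        f = waveform_features(w, sampling_rate_hz, unit_id=uid)
        feats.append(
            {
                "unit_id": uid,
                "peak_trough_ratio": f.peak_trough_ratio,
                "trough_to_peak_ms": f.trough_to_peak_ms,
                "slope_after_trough": f.slope_after_trough,
            }
        )
    fdf = pd.DataFrame(feats)
    labels, agreement = classify_spike_width(fdf, seed=seed)
    fdf["spike_class"] = labels.to_numpy()
    out = classes.merge(fdf[["unit_id", "spike_class"]], on="unit_id", how="left")
    out["agreement"] = agreement
    return out


def _nearest(grid, value):
    g = np.asarray(grid, dtype=float)
    d = np.abs((g - float(value) + 180.0) % 360.0 - 180.0)
    return float(g[int(np.argmin(d))])
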
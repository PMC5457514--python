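"""Single-unit receptive-field metrics from sorted spikes.

The pipeline follows the standard extracellular workflow for drifting
gratings: build a per-unit, per-eye response matrix over the
orientation × spatial-frequency grid (mean evoked rate minus spontaneous
rate), select each eye's preferred stimulus as the grid argmax, fit the
orientation tuning curve at the preferred SF as the sum of two equal-width
Gaussians centred on the preferred direction and its opposite over a
constant baseline,

    R(θ) = B + A1·exp(−d(θ, OPref)²/2σ²) + A2·exp(−d(θ, OPref+180°)²/2σ²),

with d the wrapped angular distance, and derive from responses and fit:

* OSI = (R_pref − R_ortho)/(R_pref + R_ortho), orthogonal = pref ± 90°
* DSI = (R_pref − R_oppo)/(R_pref + R_oppo), opposite = pref + 180°
* tuning width = half-width at half-maximum of the principal Gaussian
* ΔO = unsigned difference of the two eyes' preferred orientations on the
  180° cycle (binocular matching; 0–90°)
* ODI = (R_contra − R_ipsi)/(R_contra + R_ipsi), per-eye peak responses
* CBI = per-animal contralateral bias summary over unit ODIs

Units are included when the raw (non-baseline-subtracted) peak rate at the
dominant eye's optimal stimulus exceeds 0.5 Hz, and a cluster-quality check
flags units with ≥0.1% of spikes at interspike intervals below 1 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from binomatch._utils import circ_dist_deg, orientation_diff_deg
from binomatch.protocol import StimulusProtocol

__all__ = [
    "ResponseMatrix",
    "TuningFit",
    "compute_response_matrix",
    "select_preferred",
    "fit_orientation_tuning",
    "double_gaussian",
    "osi",
    "dsi",
    "odi",
    "tuning_width",
    "delta_orientation",
    "cbi",
    "unit_inclusion_filter",
    "isi_violation_frac",
    "analyze_units",
    "population_summary",
]

RATE_INCLUSION_HZ = 0.5      # strict: peak raw rate must exceed this
ISI_REFRACTORY_S = 1.0e-3
ISI_MAX_VIOLATION = 1.0e-3   # <0.1% of spikes below the refractory interval
SIGMA_BOUNDS_DEG = (5.0, 90.0)


# ---------------------------------------------------------------------------
# response matrices


@dataclass
class ResponseMatrix:
    """Per-unit, per-eye evoked responses on the stimulus grid.

    ``evoked_rate_hz[i, j]`` is the mean rate during presentations of
    orientation i at SF j minus the spontaneous rate (may be negative);
    ``raw_rate_hz`` is the same without baseline subtraction.
    """

    unit_id: object
    eye: str
    orientations_deg: np.ndarray
    sfs_cpd: np.ndarray
    evoked_rate_hz: np.ndarray
    raw_rate_hz: np.ndarray
    spont_rate_hz: float


def compute_response_matrix(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    protocol: StimulusProtocol,
    unit_ids=None,
) -> dict:
    """Build response matrices for every unit and eye.

    The spontaneous rate is the unit's mean rate over all blank
    presentations (both eyes pooled); each grid cell is the across-repeat
    mean of (spike count / duration) minus the spontaneous rate.

    Returns a dict keyed by ``(unit_id, eye)``.
    """
    if not trials["is_blank"].any():
        raise ValueError("no blank trials: spontaneous rate undefined")
    if unit_ids is None:
        unit_ids = np.sort(spikes["unit_id"].unique())
    unit_ids = list(unit_ids)

    oris = np.asarray(protocol.orientations_deg, dtype=float)
    sfs = np.asarray(protocol.spatial_frequencies_cpd, dtype=float)

    # spike counts per (unit, trial) as a dense array
    trial_ids = trials["trial_id"].to_numpy()
    t_index = {tid: k for k, tid in enumerate(trial_ids)}
    u_index = {uid: k for k, uid in enumerate(unit_ids)}
    counts = np.zeros((len(unit_ids), len(trials)))
    known = spikes[spikes["unit_id"].isin(u_index)]
    if len(known):
        ui = known["unit_id"].map(u_index).to_numpy()
        ti = known["trial_id"].map(t_index).to_numpy()
        if np.any(pd.isna(ti)):
            raise ValueError("spike references a trial_id absent from the trial table")
        np.add.at(counts, (ui, ti.astype(int)), 1)
    rates = counts / trials["duration_s"].to_numpy()[None, :]
    blank_mask = trials["is_blank"].to_numpy()
    spont = rates[:, blank_mask].mean(axis=1)

    # per-condition trial masks are shared across units
    cond_masks = {}
    for eye in protocol.eyes:
        eye_mask = (~blank_mask) & (trials["eye"] == eye).to_numpy()
        for i, ori in enumerate(oris):
            for j, sf in enumerate(sfs):
                sel = (
                    eye_mask
                    & (trials["orientation_deg"] == ori).to_numpy()
                    & (trials["sf_cpd"] == sf).to_numpy()
                )
                if not sel.any():
                    raise ValueError(f"no trials for eye={eye}, ori={ori}, sf={sf}")
                cond_masks[(eye, i, j)] = sel

    out = {}
    for uid in unit_ids:
        k = u_index[uid]
        for eye in protocol.eyes:
            raw = np.zeros((oris.size, sfs.size))
            for i in range(oris.size):
                for j in range(sfs.size):
                    raw[i, j] = rates[k, cond_masks[(eye, i, j)]].mean()
            out[(uid, eye)] = ResponseMatrix(
                unit_id=uid,
                eye=eye,
                orientations_deg=oris,
                sfs_cpd=sfs,
                evoked_rate_hz=raw - spont[k],
                raw_rate_hz=raw,
                spont_rate_hz=float(spont[k]),
            )
    return out


def select_preferred(rm: ResponseMatrix):
    """Grid argmax of the evoked response.

    Ties are broken toward the lowest SF, then the lowest orientation. A
    flat (all-equal) matrix returns the lowest-index condition with
    ``degenerate=True``.
    """
    ev = rm.evoked_rate_hz
    best = ev.max()
    degenerate = bool(np.isclose(ev.min(), best))
    # iterate SF-major so the first hit is lowest SF then lowest orientation
    ji = [(j, i) for j in range(ev.shape[1]) for i in range(ev.shape[0])]
    for j, i in ji:
        if ev[i, j] == best:
            return float(rm.orientations_deg[i]), float(rm.sfs_cpd[j]), degenerate
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# tuning-curve fitting


@dataclass
class TuningFit:
    """Double-Gaussian direction tuning fit (principal Gaussian first)."""

    opref_deg: float
    a1: float
    a2: float
    sigma_deg: float
    baseline_hz: float
    rss: float
    converged: bool
    degenerate: bool = False


def double_gaussian(theta_deg, opref_deg, a1, a2, sigma_deg, baseline_hz):
    """Tuning model: two equal-width Gaussians 180° apart plus baseline."""
    d1 = circ_dist_deg(theta_deg, opref_deg)
    d2 = circ_dist_deg(theta_deg, opref_deg + 180.0)
    return (
        baseline_hz
        + a1 * np.exp(-0.5 * (d1 / sigma_deg) ** 2)
        + a2 * np.exp(-0.5 * (d2 / sigma_deg) ** 2)
    )


def fit_orientation_tuning(
    orientations_deg,
    responses_hz,
    *,
    n_starts: int | None = None,
) -> TuningFit:
    """Least-squares double-Gaussian fit of a direction tuning curve.

    Multi-start bounded fit: one start per sampled direction, with the
    preferred direction constrained within ± one direction step of that
    start; σ bounded to [5°, 90°], amplitudes non-negative, baseline free.
    The best-RSS solution is canonicalized so A1 ≥ A2 (swapping shifts
    OPref by 180°).
    """
    theta = np.asarray(orientations_deg, dtype=float)
    y = np.asarray(responses_hz, dtype=float)
    if theta.size < 8:
        raise ValueError("need at least 8 direction samples")
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")

    if np.ptp(y) < 1e-12:
        return TuningFit(
            opref_deg=float(theta[0]), a1=0.0, a2=0.0, sigma_deg=30.0,
            baseline_hz=float(y.mean()), rss=0.0, converged=True, degenerate=True,
        )

    step = float(np.min(np.diff(np.sort(theta)))) if theta.size > 1 else 30.0
    starts = theta if n_starts is None else theta[:: max(1, theta.size // n_starts)]
    lo_y = float(y.min())

    def resid(p):
        return double_gaussian(theta, *p) - y

    best = None
    for d0 in starts:
        near = y[np.argmin(np.abs(circ_dist_deg(theta, d0)))]
        oppo = y[np.argmin(np.abs(circ_dist_deg(theta, d0 + 180.0)))]
        p0 = [
            float(d0),
            max(near - lo_y, 1e-3),
            max(oppo - lo_y, 1e-3),
            25.0,
            lo_y,
        ]
        bounds = (
            [d0 - step, 0.0, 0.0, SIGMA_BOUNDS_DEG[0], -np.inf],
            [d0 + step, np.inf, np.inf, SIGMA_BOUNDS_DEG[1], np.inf],
        )
        try:
            sol = least_squares(resid, p0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return TuningFit(
            opref_deg=float(theta[int(np.argmax(y))]), a1=0.0, a2=0.0,
            sigma_deg=30.0, baseline_hz=float(y.mean()), rss=float("inf"),
            converged=False,
        )
    rss, sol = best
    opref, a1, a2, sigma, b = sol.x
    if a2 > a1:
        a1, a2 = a2, a1
        opref += 180.0
    return TuningFit(
        opref_deg=float(opref % 360.0), a1=float(a1), a2=float(a2),
        sigma_deg=float(sigma), baseline_hz=float(b), rss=rss,
        converged=bool(sol.success),
    )


def tuning_width(fit: TuningFit) -> float:
    """Half-width at half-maximum of the principal Gaussian: σ√(2 ln 2)."""
    return fit.sigma_deg * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# index formulas (responses rectified at zero)


def _contrast_index(a: float, b: float) -> float:
    a = max(float(a), 0.0)
    b = max(float(b), 0.0)
    if a + b == 0.0:
        return 0.0
    return (a - b) / (a + b)


def osi(resp_pref: float, resp_ortho: float) -> float:
    """Orientation selectivity: (R_pref − R_ortho)/(R_pref + R_ortho)."""
    return _contrast_index(resp_pref, resp_ortho)


def dsi(resp_pref: float, resp_oppo: float) -> float:
    """Direction selectivity: (R_pref − R_oppo)/(R_pref + R_oppo)."""
    return _contrast_index(resp_pref, resp_oppo)


def odi(resp_contra: float, resp_ipsi: float) -> float:
    """Ocular dominance index: (R_contra − R_ipsi)/(R_contra + R_ipsi)."""
    return _contrast_index(resp_contra, resp_ipsi)


def delta_orientation(opref_contra_deg: float, opref_ipsi_deg: float) -> float:
    """Binocular mismatch ΔO on the 180° cycle, in [0, 90]."""
    return float(orientation_diff_deg(opref_contra_deg, opref_ipsi_deg))


def cbi(unit_odis, mode: str = "classes") -> float:
    """Contralateral bias index of one animal, in [0, 1].

    ``classes`` (default): bin ODIs into seven equal-width ocular-dominance
    classes on [−1, 1] (class 1 most contralateral) and apply the classical
    weighted-class formula
    [(n1 − n7) + (2/3)(n2 − n6) + (1/3)(n3 − n5) + N] / (2N).
    ``mean-odi``: (1 + mean ODI)/2.
    """
    odis = np.asarray(list(unit_odis), dtype=float)
    if odis.size == 0:
        raise ValueError("need at least one unit ODI")
    if mode == "mean-odi":
        return float((1.0 + odis.mean()) / 2.0)
    if mode != "classes":
        raise ValueError(f"unknown CBI mode: {mode!r}")
    # class 1 = ODI in (5/7, 1], ..., class 7 = ODI in [−1, −5/7)
    edges = np.linspace(-1.0, 1.0, 8)
    idx = np.clip(np.digitize(odis, edges[1:-1]), 0, 6)  # 0..6 from −1 side
    n = np.bincount(6 - idx, minlength=7)  # class 1 first
    total = odis.size
    score = (
        (n[0] - n[6]) + (2.0 / 3.0) * (n[1] - n[5]) + (1.0 / 3.0) * (n[2] - n[4]) + total
    )
    return float(score / (2.0 * total))


# ---------------------------------------------------------------------------
# QC and inclusion


def isi_violation_frac(spike_times_s, refractory_s: float = ISI_REFRACTORY_S):
    """Fraction of spikes with preceding interspike interval below 1 ms.

    Returns ``(fraction, ok)`` where ``ok`` is True when the fraction is
    below 0.1%, the cluster-quality criterion.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size < 2:
        return 0.0, True
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    frac = float(np.mean(np.diff(t) < refractory_s) * (t.size - 1) / t.size)
    return frac, frac < ISI_MAX_VIOLATION


def unit_inclusion_filter(peak_raw_rate_dominant_hz: float) -> bool:
    """Included iff the dominant eye's raw optimal-stimulus rate > 0.5 Hz."""
    return bool(peak_raw_rate_dominant_hz > RATE_INCLUSION_HZ)


# ---------------------------------------------------------------------------
# per-unit orchestration


def _resp_at(rm: ResponseMatrix, ori_deg: float, sf_cpd: float, mode: str, fit=None):
    """Evoked response at (orientation, SF), wrapped lookup or fitted value."""
    if mode == "fit" and fit is not None:
        return float(double_gaussian(ori_deg, fit.opref_deg, fit.a1, fit.a2,
                                     fit.sigma_deg, fit.baseline_hz))
    i = int(np.argmin(np.abs(circ_dist_deg(rm.orientations_deg, ori_deg))))
    j = int(np.argmin(np.abs(rm.sfs_cpd - sf_cpd)))
    return float(rm.evoked_rate_hz[i, j])


def analyze_units(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    protocol: StimulusProtocol,
    unit_ids=None,
    *,
    resp_mode: str = "raw",
) -> pd.DataFrame:
    """Full per-unit receptive-field analysis.

    For each unit and eye: preferred stimulus, double-Gaussian tuning fit
    at the preferred SF, OSI, DSI and tuning width; across eyes: ΔO, ODI,
    dominant eye and the >0.5 Hz inclusion flag; plus the ISI-violation QC
    fraction. ``resp_mode`` selects measured (``raw``) or fitted (``fit``)
    responses for the index formulas.

    Returns one row per unit (``unit_metrics`` table).
    """
    if resp_mode not in ("raw", "fit"):
        raise ValueError(f"unknown resp_mode: {resp_mode!r}")
    rms = compute_response_matrix(spikes, trials, protocol, unit_ids=unit_ids)
    uids = sorted({uid for uid, _ in rms})
    spikes_by_unit = dict(tuple(spikes.groupby("unit_id"))) if len(spikes) else {}

    rows = []
    for uid in uids:
        row = {"unit_id": uid}
        per_eye = {}
        for eye in protocol.eyes:
            rm = rms[(uid, eye)]
            ori, sf, degen = select_preferred(rm)
            j = int(np.argmin(np.abs(rm.sfs_cpd - sf)))
            curve = rm.evoked_rate_hz[:, j]
            fit = fit_orientation_tuning(rm.orientations_deg, curve)
            pref_dir = fit.opref_deg if fit.converged and not fit.degenerate else ori
            r_pref = _resp_at(rm, pref_dir, sf, resp_mode, fit)
            r_ortho = 0.5 * (
                _resp_at(rm, pref_dir + 90.0, sf, resp_mode, fit)
                + _resp_at(rm, pref_dir - 90.0, sf, resp_mode, fit)
            )
            r_oppo = _resp_at(rm, pref_dir + 180.0, sf, resp_mode, fit)
            i_pref = int(np.argmin(np.abs(circ_dist_deg(rm.orientations_deg, pref_dir))))
            per_eye[eye] = {
                "pref_sf_cpd": sf,
                "pref_dir_deg": pref_dir,
                "opref_deg": pref_dir % 180.0,
                "osi": osi(r_pref, r_ortho),
                "dsi": dsi(r_pref, r_oppo),
                "tuning_width_hwhm_deg": tuning_width(fit) if fit.converged else np.nan,
                "peak_evoked_hz": float(rm.evoked_rate_hz.max()),
                "peak_raw_hz": float(rm.raw_rate_hz[i_pref, j]),
                "fit_converged": fit.converged,
                "degenerate": degen or fit.degenerate,
            }
            for k, v in per_eye[eye].items():
                row[f"{eye}_{k}"] = v
        row["spont_rate_hz"] = rms[(uid, protocol.eyes[0])].spont_rate_hz
        row["delta_o_deg"] = delta_orientation(
            per_eye["contra"]["opref_deg"], per_eye["ipsi"]["opref_deg"]
        )
        row["odi"] = odi(
            per_eye["contra"]["peak_evoked_hz"], per_eye["ipsi"]["peak_evoked_hz"]
        )
        dominant = "contra" if per_eye["contra"]["peak_evoked_hz"] >= per_eye["ipsi"]["peak_evoked_hz"] else "ipsi"
        row["dominant_eye"] = dominant
        row["included"] = unit_inclusion_filter(per_eye[dominant]["peak_raw_hz"])
        if uid in spikes_by_unit:
            # ISI QC is evaluated within trials; relative times across trials
            # are not consecutive, so compute per trial
            nsp = 0
            viol = 0
            for _, g in spikes_by_unit[uid].groupby("trial_id"):
                tt = np.sort(g["t_rel_s"].to_numpy())
                if tt.size >= 2:
                    viol += int(np.sum(np.diff(tt) < ISI_REFRACTORY_S))
                nsp += tt.size
            row["isi_violation_frac"] = viol / nsp if nsp else 0.0
        else:
            row["isi_violation_frac"] = 0.0
        row["isi_ok"] = row["isi_violation_frac"] < ISI_MAX_VIOLATION
        rows.append(row)
    return pd.DataFrame(rows)


def population_summary(
    unit_metrics: pd.DataFrame,
    animal_ids=None,
    *,
    cbi_mode: str = "classes",
    included_only: bool = True,
) -> tuple:
    """By-case and pooled summaries.

    ``animal_ids`` maps each row of ``unit_metrics`` to an animal (defaults
    to a single animal). Returns ``(per_animal, pooled)`` where per_animal
    has mean/median ΔO, CBI and unit count per animal, and pooled is one
    row over all (included) units.
    """
    df = unit_metrics.copy()
    df["animal_id"] = animal_ids if animal_ids is not None else 0
    if included_only:
        df = df[df["included"]]
    if df.empty:
        raise ValueError("no included units")
    per_animal = (
        df.groupby("animal_id")
        .apply(
            lambda g: pd.Series(
                {
                    "mean_delta_o_deg": g["delta_o_deg"].mean(),
                    "median_delta_o_deg": g["delta_o_deg"].median(),
                    "cbi": cbi(g["odi"], mode=cbi_mode),
                    "n_units": len(g),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    pooled = pd.Series(
        {
            "mean_delta_o_deg": df["delta_o_deg"].mean(),
            "median_delta_o_deg": df["delta_o_deg"].median(),
            "mean_odi": df["odi"].mean(),
            "n_units": len(df),
        }
    )
    return per_animal, pooled
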
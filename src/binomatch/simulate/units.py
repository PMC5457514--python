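"""Simulate binocular, orientation-tuned spiking populations.

The rate model mirrors the analysis-side tuning model: for each eye a unit's
evoked rate over direction θ is the sum of two equal-width Gaussians centred
on the preferred direction and its opposite, scaled by a log-Gaussian
spatial-frequency envelope around a per-unit preferred SF. Spikes are drawn
from a piecewise-constant-rate Poisson process on 1 ms sub-bins. Simple
cells are additionally modulated at the grating temporal frequency with a
half-rectified sinusoidal profile; complex cells fire at a constant
within-trial rate.

Binocular mismatch is controlled by the ``mismatch_model``:

``matched``
    The ipsi−contra orientation offset is drawn from a von Mises
    distribution on the 180° orientation cycle with concentration ``kappa``
    (large κ → well matched eyes, as in wild-type animals).
``uniform``
    The offset is uniform on the cycle, so the true binocular mismatch ΔO
    is uniform on [0, 90]° (a fully unmatched population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from binomatch._utils import circ_dist_deg, orientation_diff_deg
from binomatch.protocol import StimulusProtocol, make_stimulus_protocol

__all__ = ["SimulatedPopulation", "simulate_unit_population", "make_waveform_template"]

SUBBIN_S = 0.001  # piecewise-constant Poisson resolution

# Waveform template defaults (trough-to-peak times per spike class)
NARROW_TTP_MS = 0.25
BROAD_TTP_MS = 0.55
WAVEFORM_RATE_HZ = 30000.0
WAVEFORM_DUR_MS = 1.0


@dataclass
class SimulatedPopulation:
    """Bundle of generator outputs: ground truth plus raw-data tables."""

    truth: pd.DataFrame
    spikes: pd.DataFrame
    trials: pd.DataFrame
    waveforms: pd.DataFrame
    meta: dict
    protocol: StimulusProtocol


def make_waveform_template(
    trough_to_peak_ms: float,
    peak_trough_ratio: float = 0.45,
    sampling_rate_hz: float = WAVEFORM_RATE_HZ,
    duration_ms: float = WAVEFORM_DUR_MS,
    trough_time_ms: float = 0.2,
) -> np.ndarray:
    """Biphasic extracellular spike template (negative trough, later peak).

    The template is the difference of two Gaussians: a fixed-width trough at
    ``trough_time_ms`` and a broader positive afterpotential whose maximum
    lags the trough by ``trough_to_peak_ms``. Amplitudes are normalized so
    the trough depth is 1.
    """
    n = int(round(duration_ms * 1e-3 * sampling_rate_hz)) + 1
    t_ms = np.arange(n) / sampling_rate_hz * 1e3
    trough = -np.exp(-0.5 * ((t_ms - trough_time_ms) / 0.06) ** 2)
    peak_t = trough_time_ms + trough_to_peak_ms
    peak = peak_trough_ratio * np.exp(
        -0.5 * ((t_ms - peak_t) / (0.35 * trough_to_peak_ms + 0.05)) ** 2
    )
    w = trough + peak
    return w / np.abs(w.min())


def _rectified_drift_profile(
    modulation_depth: float, tf_hz: float, duration_s: float
) -> np.ndarray:
    """Within-trial rate profile g(t) on 1 ms bins, normalized to mean 1.

    g(t) ∝ max(0, (1−m) + m·cos(2π f t)); m=0 gives a flat profile, m=1 a
    half-rectified cosine (the textbook simple-cell profile with F1/F0=π/2).
    """
    n = int(round(duration_s / SUBBIN_S))
    t = (np.arange(n) + 0.5) * SUBBIN_S
    h = np.maximum(0.0, (1.0 - modulation_depth) + modulation_depth * np.cos(2 * np.pi * tf_hz * t))
    m = h.mean()
    if m <= 0:
        return np.ones(n)
    return h / m


def _draw_orientation_offset(rng, model: str, kappa: float, size: int) -> np.ndarray:
    """Ipsi−contra preferred-orientation offset in degrees, in (−90, 90]."""
    if model == "matched":
        ang = rng.vonmises(0.0, kappa, size=size)  # radians on (−π, π]
        return ang * (90.0 / np.pi)
    if model == "uniform":
        return rng.uniform(-90.0, 90.0, size=size)
    raise ValueError(f"unknown mismatch_model: {model!r}")


def _build_trial_table(protocol: StimulusProtocol, rng) -> pd.DataFrame:
    rows = []
    for eye in protocol.eyes:
        conds = [
            (ori, sf)
            for ori in protocol.orientations_deg
            for sf in protocol.spatial_frequencies_cpd
        ] * protocol.repeats_per_eye
        blanks = [(np.nan, np.nan)] * (protocol.n_blank_conditions * protocol.repeats_per_eye)
        all_conds = conds + blanks
        order = rng.permutation(len(all_conds))
        for k in order:
            ori, sf = all_conds[k]
            rows.append((eye, ori, sf, np.isnan(ori), protocol.stim_duration_s))
    trials = pd.DataFrame(
        rows, columns=["eye", "orientation_deg", "sf_cpd", "is_blank", "duration_s"]
    )
    trials.insert(0, "trial_id", np.arange(len(trials)))
    return trials


def simulate_unit_population(
    n_units: int,
    mismatch_model: str = "matched",
    protocol: StimulusProtocol | None = None,
    seed: int | None = None,
    *,
    kappa: float = 20.0,
    frac_simple: float = 0.5,
    frac_narrow: float = 0.25,
    simple_modulation: float = 0.9,
    sf_sigma_dex: float = 0.25,
    peak_rate_median_hz: float = 10.0,
    peak_rate_sigma_log: float = 0.4,
    waveform_noise_sd: float = 0.03,
) -> SimulatedPopulation:
    """Simulate a recorded population under the grating protocol.

    Parameters
    ----------
    n_units
        Number of single units.
    mismatch_model
        ``"matched"`` (von Mises offset with concentration ``kappa``) or
        ``"uniform"`` (offset uniform on the orientation cycle).
    protocol
        Stimulation protocol; defaults to the standard 12-direction ×
        6-SF × 5-repeat battery.
    seed
        Seed for the generator; identical seeds give bit-identical outputs.
    kappa
        Concentration of the matched-offset distribution (ignored for
        ``uniform``). The default 20 gives a mean true ΔO of about 5°.
    frac_simple, frac_narrow
        Expected fractions of simple cells and narrow-spiking units.
    simple_modulation
        Ground-truth modulation depth of simple cells (complex cells get 0).
    sf_sigma_dex
        Width (decades) of the log-Gaussian SF envelope.
    peak_rate_median_hz, peak_rate_sigma_log
        Log-normal peak evoked rate distribution across units.
    waveform_noise_sd
        Gaussian sample noise added to the waveform templates (in units of
        trough depth).

    Returns
    -------
    SimulatedPopulation
        Ground-truth unit table, spike-event table, trial table, waveform
        table and metadata.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if mismatch_model not in ("matched", "uniform"):
        raise ValueError(f"unknown mismatch_model: {mismatch_model!r}")
    rng = np.random.default_rng(seed)
    proto = protocol or make_stimulus_protocol()

    trials = _build_trial_table(proto, rng)

    # --- ground truth -----------------------------------------------------
    pref_dir_contra = rng.uniform(0, 360, n_units)
    offset = _draw_orientation_offset(rng, mismatch_model, kappa, n_units)
    flip = rng.integers(0, 2, n_units) * 180.0
    pref_dir_ipsi = (pref_dir_contra + offset + flip) % 360.0
    sigma_deg = rng.uniform(15.0, 35.0, n_units)
    if peak_rate_median_hz == 0:
        peak_rate = np.zeros(n_units)  # degenerate: spontaneous spikes only
    else:
        peak_rate = rng.lognormal(
            np.log(peak_rate_median_hz), peak_rate_sigma_log, n_units
        )
    spont_rate = rng.uniform(0.2, 2.0, n_units)
    a2_ratio = rng.uniform(0.0, 0.7, n_units)  # opposite-direction amplitude ratio
    odi_true = np.clip(rng.normal(0.2, 0.3, n_units), -0.9, 0.9)
    pref_sf = rng.choice(proto.spatial_frequencies_cpd, size=n_units)
    cell_type = np.where(rng.random(n_units) < frac_simple, "simple", "complex")
    spike_class = np.where(rng.random(n_units) < frac_narrow, "narrow", "broad")
    modulation = np.where(cell_type == "simple", simple_modulation, 0.0)

    truth = pd.DataFrame(
        {
            "unit_id": np.arange(n_units),
            "pref_direction_contra_deg": pref_dir_contra,
            "pref_direction_ipsi_deg": pref_dir_ipsi,
            "opref_contra_deg": pref_dir_contra % 180.0,
            "opref_ipsi_deg": pref_dir_ipsi % 180.0,
            "sigma_deg": sigma_deg,
            "peak_rate_hz": peak_rate,
            "spont_rate_hz": spont_rate,
            "a2_ratio": a2_ratio,
            "odi_true": odi_true,
            "pref_sf_cpd": pref_sf,
            "cell_type": cell_type,
            "spike_class": spike_class,
            "modulation_depth": modulation,
        }
    )
    truth["delta_o_true_deg"] = orientation_diff_deg(
        truth["opref_contra_deg"], truth["opref_ipsi_deg"]
    )

    # --- spikes -----------------------------------------------------------
    # Eye gains chosen so the peak-response ODI equals odi_true while the
    # dominant eye's peak evoked rate equals peak_rate_hz.
    gain_contra = (1.0 + odi_true) / (1.0 + np.abs(odi_true))
    gain_ipsi = (1.0 - odi_true) / (1.0 + np.abs(odi_true))

    dur = proto.stim_duration_s
    nbins = int(round(dur / SUBBIN_S))
    is_stim = ~trials["is_blank"].to_numpy()
    tr_eye = trials["eye"].to_numpy()
    tr_ori = trials["orientation_deg"].to_numpy(dtype=float)
    tr_sf = trials["sf_cpd"].to_numpy(dtype=float)
    n_trials = len(trials)

    spike_chunks = []
    flat_profile = np.ones(nbins)
    for u in range(n_units):
        # mean evoked amplitude for every trial (Hz)
        pref_dir = np.where(tr_eye == "contra", pref_dir_contra[u], pref_dir_ipsi[u])
        gain = np.where(tr_eye == "contra", gain_contra[u], gain_ipsi[u])
        d1 = circ_dist_deg(tr_ori, pref_dir)
        d2 = circ_dist_deg(tr_ori, pref_dir + 180.0)
        tune = np.exp(-0.5 * (d1 / sigma_deg[u]) ** 2) + a2_ratio[u] * np.exp(
            -0.5 * (d2 / sigma_deg[u]) ** 2
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            env = np.exp(
                -0.5 * (np.log10(tr_sf / pref_sf[u]) / sf_sigma_dex) ** 2
            )
        amp = np.where(is_stim, peak_rate[u] * gain * tune * env, 0.0)

        if modulation[u] > 0:
            profile = _rectified_drift_profile(
                modulation[u], proto.temporal_frequency_hz, dur
            )
        else:
            profile = flat_profile
        rate = spont_rate[u] + amp[:, None] * profile[None, :]
        counts = rng.poisson(rate * SUBBIN_S)
        trial_idx, bin_idx = np.nonzero(counts)
        reps = counts[trial_idx, bin_idx]
        trial_idx = np.repeat(trial_idx, reps)
        bin_idx = np.repeat(bin_idx, reps)
        t_rel = (bin_idx + rng.random(bin_idx.size)) * SUBBIN_S
        order = np.lexsort((t_rel, trial_idx))
        spike_chunks.append(
            pd.DataFrame(
                {
                    "unit_id": np.full(trial_idx.size, u),
                    "trial_id": trials["trial_id"].to_numpy()[trial_idx[order]],
                    "t_rel_s": t_rel[order],
                }
            )
        )
    spikes = pd.concat(spike_chunks, ignore_index=True)

    # --- waveforms --------------------------------------------------------
    wf_rows = []
    for u in range(n_units):
        ttp = NARROW_TTP_MS if spike_class[u] == "narrow" else BROAD_TTP_MS
        ptr = 0.30 if spike_class[u] == "narrow" else 0.50
        w = make_waveform_template(ttp, peak_trough_ratio=ptr)
        w = w + rng.normal(0.0, waveform_noise_sd, w.size)
        wf_rows.append(
            pd.DataFrame(
                {"unit_id": u, "sample_idx": np.arange(w.size), "amplitude": w}
            )
        )
    waveforms = pd.concat(wf_rows, ignore_index=True)

    meta = {
        "sampling_rate_hz": WAVEFORM_RATE_HZ,
        "n_units": n_units,
        "n_trials": n_trials,
        "mismatch_model": mismatch_model,
        "seed": seed,
    }
    return SimulatedPopulation(truth, spikes, trials, waveforms, meta, proto)
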
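"""Receptive-field metrics: formulas, fits, filters, and recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binomatch import tuning
from binomatch.protocol import make_stimulus_protocol
from tests.conftest import make_trials


# ---------------------------------------------------------------------------
# response matrices


def spikes_df(rows):
    return pd.DataFrame(rows, columns=["unit_id", "trial_id", "t_rel_s"])


def test_silent_unit_yields_zero_matrix(protocol):
    trials = make_trials(protocol)
    rms = tuning.compute_response_matrix(
        spikes_df([]), trials, protocol, unit_ids=[0]
    )
    rm = rms[(0, "contra")]
    assert np.all(rm.evoked_rate_hz == 0)
    assert rm.spont_rate_hz == 0


def test_evoked_rate_is_count_over_duration_minus_spontaneous(protocol):
    trials = make_trials(protocol)
    target = trials[
        (~trials.is_blank)
        & (trials.eye == "contra")
        & (trials.orientation_deg == 0.0)
        & (trials.sf_cpd == 0.01)
    ]
    assert len(target) == 5
    rows = []
    for tid in target.trial_id:
        rows += [(0, tid, 0.1 * (k + 1)) for k in range(3)]  # 3 spikes per repeat
    rms = tuning.compute_response_matrix(spikes_df(rows), trials, protocol)
    rm = rms[(0, "contra")]
    assert rm.evoked_rate_hz[0, 0] == pytest.approx(3 / 1.5)
    assert rm.spont_rate_hz == 0


def test_spontaneous_rate_averages_blank_presentations(protocol):
    trials = make_trials(protocol)
    blanks = trials[trials.is_blank].trial_id.to_numpy()
    rows = [(0, tid, 0.5) for tid in blanks]  # 1 spike every blank
    rms = tuning.compute_response_matrix(spikes_df(rows), trials, protocol)
    rm = rms[(0, "ipsi")]
    assert rm.spont_rate_hz == pytest.approx(1 / 1.5)
    # evoked entries are baseline-subtracted and may be negative
    assert np.all(rm.evoked_rate_hz == pytest.approx(-1 / 1.5))


def test_missing_blanks_is_an_error(protocol):
    trials = make_trials(protocol)
    with pytest.raises(ValueError, match="blank"):
        tuning.compute_response_matrix(
            spikes_df([]), trials[~trials.is_blank], protocol, unit_ids=[0]
        )


def test_response_matrix_matches_generator_at_many_repeats():
    proto = make_stimulus_protocol(
        {"repeats_per_eye": 200, "spatial_frequencies_cpd": (0.04,)}
    )
    from binomatch.simulate import simulate_unit_population

    pop = simulate_unit_population(1, "matched", protocol=proto, seed=13)
    rms = tuning.compute_response_matrix(pop.spikes, pop.trials, proto)
    u = pop.truth.iloc[0]
    rm = rms[(0, "contra")]
    from binomatch._utils import circ_dist_deg

    gain = (1 + u.odi_true) / (1 + abs(u.odi_true))
    for i, ori in enumerate(rm.orientations_deg):
        d1 = float(circ_dist_deg(ori, u.pref_direction_contra_deg))
        d2 = float(circ_dist_deg(ori, u.pref_direction_contra_deg + 180))
        tune = np.exp(-0.5 * (d1 / u.sigma_deg) ** 2) + u.a2_ratio * np.exp(
            -0.5 * (d2 / u.sigma_deg) ** 2
        )
        env = np.exp(-0.5 * (np.log10(0.04 / u.pref_sf_cpd) / 0.25) ** 2)
        expected = u.peak_rate_hz * gain * tune * env
        se = np.sqrt((expected + u.spont_rate_hz) / (200 * proto.stim_duration_s))
        assert abs(rm.evoked_rate_hz[i, 0] - expected) < 3.5 * se + 0.05


# ---------------------------------------------------------------------------
# preferred-stimulus selection


def _rm(evoked, oris=None, sfs=None):
    oris = np.asarray(oris if oris is not None else np.arange(0, 360, 30), float)
    sfs = np.asarray(sfs if sfs is not None else [0.01, 0.02, 0.04, 0.08, 0.16, 0.32])
    ev = np.asarray(evoked, float)
    return tuning.ResponseMatrix("u", "contra", oris, sfs, ev, ev, 0.0)


def test_single_peak_selected():
    ev = np.zeros((12, 6))
    ev[3, 2] = 5.0
    ori, sf, degen = tuning.select_preferred(_rm(ev))
    assert (ori, sf) == (90.0, 0.04)
    assert not degen


def test_tie_broken_toward_lowest_sf_then_orientation():
    ev = np.zeros((12, 6))
    ev[4, 3] = 5.0  # SF 0.08
    ev[7, 1] = 5.0  # SF 0.02 wins
    ori, sf, _ = tuning.select_preferred(_rm(ev))
    assert (ori, sf) == (210.0, 0.02)


def test_flat_matrix_flagged_degenerate():
    ori, sf, degen = tuning.select_preferred(_rm(np.full((12, 6), 2.0)))
    assert (ori, sf) == (0.0, 0.01)
    assert degen


# ---------------------------------------------------------------------------
# double-Gaussian fits


def test_noise_free_parameters_recovered_to_1e3():
    theta = np.arange(0, 360, 30)
    y = tuning.double_gaussian(theta, 60, 10, 4, 20, 1)
    fit = tuning.fit_orientation_tuning(theta, y)
    assert fit.converged
    assert abs(fit.opref_deg - 60) <= 1e-3
    assert abs(fit.a1 - 10) <= 1e-3
    assert abs(fit.a2 - 4) <= 1e-3
    assert abs(fit.sigma_deg - 20) <= 1e-3
    assert abs(fit.baseline_hz - 1) <= 1e-3
    assert fit.a1 >= fit.a2 >= 0


def test_flat_curve_returns_baseline_with_degenerate_flag():
    theta = np.arange(0, 360, 30)
    fit = tuning.fit_orientation_tuning(theta, np.full(12, 2.0))
    assert fit.degenerate
    assert fit.a1 == fit.a2 == 0
    assert fit.baseline_hz == pytest.approx(2.0)


def test_too_few_or_nonfinite_samples_rejected():
    with pytest.raises(ValueError):
        tuning.fit_orientation_tuning(np.arange(0, 360, 60), np.ones(6))
    theta = np.arange(0, 360, 30)
    y = np.ones(12)
    y[3] = np.nan
    with pytest.raises(ValueError):
        tuning.fit_orientation_tuning(theta, y)


def test_opref_equals_brute_force_grid_search_on_noise_free_input():
    """The free-OPref fit lands within one 1°-grid step of an exhaustive
    fixed-OPref search."""
    from scipy.optimize import least_squares

    theta = np.arange(0, 360, 30)
    for true_op in (13.0, 155.0, 301.0):
        y = tuning.double_gaussian(theta, true_op, 8, 2, 25, 0.5)
        fit = tuning.fit_orientation_tuning(theta, y)
        best = (np.inf, None)
        for op in np.arange(0.0, 360.0, 1.0):
            sol = least_squares(
                lambda p: tuning.double_gaussian(theta, op, *p) - y,
                [6.0, 2.0, 25.0, 0.0],
                bounds=([0, 0, 5, -np.inf], [np.inf, np.inf, 90, np.inf]),
            )
            rss = float(np.sum(sol.fun**2))
            if rss < best[0]:
                best = (rss, op, sol.x)
        grid_op = best[1]
        if best[2][1] > best[2][0]:  # canonicalize grid solution (A1 >= A2)
            grid_op = (grid_op + 180.0) % 360.0
        diff = abs((fit.opref_deg - grid_op + 180) % 360 - 180)
        assert diff <= 1.0


def test_tuning_width_closed_form():
    fit = tuning.TuningFit(0, 1, 0, 20.0, 0, 0, True)
    assert tuning.tuning_width(fit) == pytest.approx(20 * np.sqrt(2 * np.log(2)))
    fit_small = tuning.TuningFit(0, 1, 0, 1e-9, 0, 0, True)
    assert tuning.tuning_width(fit_small) < 1e-6


# ---------------------------------------------------------------------------
# index formulas


@pytest.mark.parametrize(
    "fn,a,b,expected",
    [
        (tuning.osi, 10, 0, 1.0),
        (tuning.osi, 10, 10, 0.0),
        (tuning.osi, 8, 2, 0.6),
        (tuning.dsi, 10, 0, 1.0),
        (tuning.dsi, 6, 6, 0.0),
        (tuning.dsi, 9, 3, 0.5),
        (tuning.odi, 10, 0, 1.0),
        (tuning.odi, 5, 5, 0.0),
        (tuning.odi, 2, 6, -0.5),
    ],
)
def test_selectivity_index_formulas(fn, a, b, expected):
    assert fn(a, b) == pytest.approx(expected)


def test_indexes_zero_when_both_responses_zero_or_negative():
    assert tuning.osi(0, 0) == 0.0
    assert tuning.odi(-1.0, -2.0) == 0.0  # rectified at zero first


@given(
    a=st.floats(0, 100),
    b=st.floats(0, 100),
    c=st.floats(0.01, 100),
)
@settings(max_examples=50, deadline=None)
def test_indexes_scale_invariant(a, b, c):
    assert tuning.osi(a, b) == pytest.approx(tuning.osi(c * a, c * b), abs=1e-12)
    assert tuning.odi(a, b) == pytest.approx(tuning.odi(c * a, c * b), abs=1e-12)


@pytest.mark.parametrize(
    "c,i,expected", [(10, 170, 20), (45, 45, 0), (0, 90, 90), (178, 2, 4)]
)
def test_delta_orientation_wraps_on_180_cycle(c, i, expected):
    assert tuning.delta_orientation(c, i) == pytest.approx(expected)


@given(
    a=st.floats(0, 360, allow_nan=False),
    b=st.floats(0, 360, allow_nan=False),
)
@settings(max_examples=100, deadline=None)
def test_delta_orientation_symmetric_and_period_invariant(a, b):
    d = tuning.delta_orientation(a, b)
    assert 0 <= d <= 90
    assert d == pytest.approx(tuning.delta_orientation(b, a), abs=1e-9)
    assert d == pytest.approx(tuning.delta_orientation(a + 180, b), abs=1e-9)


# ---------------------------------------------------------------------------
# CBI


def test_cbi_extremes_and_symmetry():
    assert tuning.cbi([1.0] * 5) == pytest.approx(1.0)
    assert tuning.cbi([-1.0] * 5) == pytest.approx(0.0)
    assert tuning.cbi([1.0, -1.0]) == pytest.approx(0.5)
    assert tuning.cbi([1.0, -1.0], mode="mean-odi") == pytest.approx(0.5)
    assert tuning.cbi([1.0] * 3, mode="mean-odi") == pytest.approx(1.0)


def test_cbi_bounded_on_random_odis():
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = tuning.cbi(rng.uniform(-1, 1, 30))
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# inclusion and ISI QC


@pytest.mark.parametrize("rate,included", [(0.4, False), (0.5, False), (0.6, True)])
def test_inclusion_threshold_is_strict_at_half_hz(rate, included):
    assert tuning.unit_inclusion_filter(rate) is included


def test_isi_violations_counted_against_total_spikes():
    frac, ok = tuning.isi_violation_frac([0.0, 0.0005, 1.0])
    assert frac == pytest.approx(1 / 3)
    assert not ok
    frac, ok = tuning.isi_violation_frac(np.arange(0, 60, 0.1))
    assert frac == 0.0
    assert ok


def test_poisson_train_violation_fraction_matches_analytic_rate():
    rng = np.random.default_rng(12)
    rate, dur = 5.0, 600.0
    t = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
    frac, ok = tuning.isi_violation_frac(t)
    expected = 1 - np.exp(-rate * 1e-3)  # P(interval < 1 ms)
    assert frac == pytest.approx(expected, rel=0.35)
    assert not ok


# ---------------------------------------------------------------------------
# population-level recovery


def test_pipeline_recovers_preferred_condition_and_mismatch(small_pop, small_metrics):
    merged = small_metrics.merge(small_pop.truth, on="unit_id")
    # preferred SF recovered for most units
    sf_match = (merged["contra_pref_sf_cpd"] == merged["pref_sf_cpd"]).mean()
    assert sf_match >= 0.8
    err = np.minimum(
        (merged["contra_opref_deg"] - merged["opref_contra_deg"]) % 180,
        180 - (merged["contra_opref_deg"] - merged["opref_contra_deg"]) % 180,
    )
    assert np.median(err) < 10
    assert (merged["delta_o_deg"].between(0, 90)).all()
    assert (merged["odi"].between(-1, 1)).all()
    # estimated ODI tracks ground truth
    assert np.corrcoef(merged["odi"], merged["odi_true"])[0, 1] > 0.7


def test_population_summary_matches_brute_force_grouping(small_metrics):
    animals = np.arange(len(small_metrics)) % 3
    per_animal, pooled = tuning.population_summary(small_metrics, animals)
    df = small_metrics.assign(animal_id=animals)
    df = df[df.included]
    for aid, g in df.groupby("animal_id"):
        row = per_animal[per_animal.animal_id == aid].iloc[0]
        assert row["mean_delta_o_deg"] == pytest.approx(g["delta_o_deg"].mean())
        assert row["n_units"] == len(g)
    assert pooled["n_units"] == len(df)
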
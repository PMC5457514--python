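"""Generator contracts: determinism, ground-truth statistics, rate model."""

import numpy as np
import pandas as pd
import pytest

from binomatch._utils import circ_dist_deg
from binomatch.behavior import ArenaGeometry
from binomatch.protocol import make_stimulus_protocol
from binomatch.simulate import (
    simulate_expression,
    simulate_trajectory,
    simulate_unit_population,
    simulate_vep_session,
)


# ---------------------------------------------------------------------------
# spiking populations


def test_same_seed_reproduces_identical_population():
    a = simulate_unit_population(5, "matched", seed=42)
    b = simulate_unit_population(5, "matched", seed=42)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.spikes, b.spikes)
    pd.testing.assert_frame_equal(a.trials, b.trials)
    pd.testing.assert_frame_equal(a.waveforms, b.waveforms)


def test_matched_population_has_small_true_mismatch():
    pop = simulate_unit_population(
        100, "matched", protocol=make_stimulus_protocol({"repeats_per_eye": 1}), seed=3
    )
    assert pop.truth["delta_o_true_deg"].mean() < 10.0


def test_uniform_population_mismatch_centred_at_45():
    proto = make_stimulus_protocol({"repeats_per_eye": 1})
    pop = simulate_unit_population(400, "uniform", protocol=proto, seed=5)
    d = pop.truth["delta_o_true_deg"]
    sem = d.std() / np.sqrt(len(d))
    assert abs(d.mean() - 45.0) < 3 * sem
    assert d.between(0, 90).all()


def test_unknown_mismatch_model_rejected():
    with pytest.raises(ValueError, match="mismatch_model"):
        simulate_unit_population(2, "banana", seed=0)


def test_zero_peak_rate_units_fire_at_spontaneous_rate_only():
    proto = make_stimulus_protocol({"repeats_per_eye": 2})
    pop = simulate_unit_population(
        4, "matched", protocol=proto, seed=9, peak_rate_median_hz=0.0
    )
    total_time = len(pop.trials) * proto.stim_duration_s
    rates = pop.spikes.groupby("unit_id").size() / total_time
    spont = pop.truth.set_index("unit_id")["spont_rate_hz"]
    for uid, r in rates.items():
        se = np.sqrt(spont[uid] / total_time)
        assert abs(r - spont[uid]) < 4 * se + 1e-9


def test_trial_table_covers_grid_and_blanks(small_pop):
    proto = small_pop.protocol
    trials = small_pop.trials
    assert len(trials) == proto.n_stimulus_trials + proto.n_blank_trials
    stim = trials[~trials.is_blank]
    per_cond = stim.groupby(["eye", "orientation_deg", "sf_cpd"]).size()
    assert (per_cond == proto.repeats_per_eye).all()
    assert trials[trials.is_blank]["orientation_deg"].isna().all()
    assert (small_pop.spikes["t_rel_s"] >= 0).all()
    assert (small_pop.spikes["t_rel_s"] <= proto.stim_duration_s).all()


def test_empirical_rates_converge_to_generator_rate_function():
    """At 200 repeats the per-condition mean rates match the rate model."""
    proto = make_stimulus_protocol(
        {"repeats_per_eye": 200, "spatial_frequencies_cpd": (0.04, 0.08)}
    )
    pop = simulate_unit_population(2, "matched", protocol=proto, seed=21)
    tr = pop.trials
    for _, u in pop.truth.iterrows():
        counts_u = (
            pop.spikes[pop.spikes["unit_id"] == u.unit_id].groupby("trial_id").size()
        )
        mine = tr.assign(n=tr["trial_id"].map(counts_u))
        for (eye, ori, sf), g in mine[~mine.is_blank].groupby(
            ["eye", "orientation_deg", "sf_cpd"]
        ):
            pref = (
                u.pref_direction_contra_deg if eye == "contra" else u.pref_direction_ipsi_deg
            )
            gain = (1 + u.odi_true) if eye == "contra" else (1 - u.odi_true)
            gain /= 1 + abs(u.odi_true)
            d1 = float(circ_dist_deg(ori, pref))
            d2 = float(circ_dist_deg(ori, pref + 180))
            tune = np.exp(-0.5 * (d1 / u.sigma_deg) ** 2) + u.a2_ratio * np.exp(
                -0.5 * (d2 / u.sigma_deg) ** 2
            )
            env = np.exp(-0.5 * (np.log10(sf / u.pref_sf_cpd) / 0.25) ** 2)
            expected = u.spont_rate_hz + u.peak_rate_hz * gain * tune * env
            obs = g["n"].fillna(0).mean() / proto.stim_duration_s
            se = np.sqrt(expected / (len(g) * proto.stim_duration_s))
            assert abs(obs - expected) < 3.5 * se + 0.05


def test_simple_cells_are_modulated_and_complex_cells_flat(small_pop):
    """Within-trial spike-time histograms show drift-frequency modulation
    only for ground-truth simple cells."""
    proto = small_pop.protocol
    spikes = small_pop.spikes.merge(small_pop.trials, on="trial_id")
    stim = spikes[~spikes.is_blank]
    phase = (stim["t_rel_s"] * proto.temporal_frequency_hz) % 1.0
    stim = stim.assign(phase=phase)
    for ctype, expect_mod in (("simple", True), ("complex", False)):
        uids = small_pop.truth.loc[small_pop.truth.cell_type == ctype, "unit_id"]
        sub = stim[stim.unit_id.isin(uids)]
        hist, _ = np.histogram(sub["phase"], bins=8)
        depth = (hist.max() - hist.min()) / hist.mean()
        if expect_mod:
            assert depth > 0.5
        else:
            assert depth < 0.2


# ---------------------------------------------------------------------------
# VEP sessions


def test_noise_free_vep_amplitudes_vanish_above_cutoff():
    # zero crossing at 0.6 c/deg: intercept = −slope·log10(0.6)
    slope = -50.0
    intercept = slope * -np.log10(0.6)
    amps = simulate_vep_session(slope, intercept, noise_sd=0.0, seed=0)
    contra = amps[amps.eye == "contra"].set_index("sf_cpd")["p1_uv"]
    assert contra[0.96] == 0.0
    assert (contra[contra.index < 0.6] > 0).all()


def test_ci_ratio_exact_without_noise():
    amps = simulate_vep_session(-50.0, 10.0, ci_ratio_true=2.0, noise_sd=0.0, seed=0)
    piv = amps.pivot(index="sf_cpd", columns="eye", values="p1_uv")
    nz = piv[piv["ipsi"] > 0]
    assert np.allclose(nz["contra"] / nz["ipsi"], 2.0)


def test_vep_session_deterministic_given_seed():
    a = simulate_vep_session(-50.0, 10.0, noise_sd=5.0, seed=8)
    b = simulate_vep_session(-50.0, 10.0, noise_sd=5.0, seed=8)
    pd.testing.assert_frame_equal(a, b)


def test_positive_slope_rejected():
    with pytest.raises(ValueError, match="slope"):
        simulate_vep_session(1.0, 0.0, seed=0)


# ---------------------------------------------------------------------------
# expression matrices


def test_null_expression_has_no_true_de_genes():
    m, groups, truth = simulate_expression(200, 4, 50, effect_log2fc=0.0, seed=1)
    assert truth["de_genes"] == set()
    ga = [c for c, g in groups.items() if g == "groupA"]
    gb = [c for c, g in groups.items() if g == "groupB"]
    ratios = np.log2(m[gb].mean(axis=1)) - np.log2(m[ga].mean(axis=1))
    assert abs(ratios.mean()) < 0.1


def test_target_genes_show_the_designed_fold_change():
    m, groups, truth = simulate_expression(
        500, 4, 60, effect_log2fc=2.0, dispersion=0.05, seed=2
    )
    ga = [c for c, g in groups.items() if g == "groupA"]
    gb = [c for c, g in groups.items() if g == "groupB"]
    lfc = np.log2(m[ga].mean(axis=1)) - np.log2(m[gb].mean(axis=1))
    on_target = lfc[sorted(truth["target_genes"])]
    assert np.allclose(2.0**on_target, 4.0, rtol=0.35)
    assert abs(on_target.mean() - 2.0) < 0.1


def test_default_replicate_design_is_four_per_group():
    m, groups, _ = simulate_expression(50, seed=0)
    counts = pd.Series(groups).value_counts()
    assert (counts == 4).all()


# ---------------------------------------------------------------------------
# trajectories


def test_trajectory_confined_to_arena_bounds():
    arena = ArenaGeometry()
    traj = simulate_trajectory(arena, side_bias=0.3, duration_s=60, seed=4)
    assert traj["x_cm"].between(0, 50).all()
    assert traj["y_cm"].between(0, 36).all()
    assert np.allclose(np.diff(traj["t_s"]), 0.1)


def test_full_shallow_bias_is_absorbing():
    traj = simulate_trajectory(side_bias=1.0, duration_s=120, seed=6)
    # after an initial transient the animal never leaves the shallow half
    tail = traj[traj["t_s"] > 30]
    assert (tail["x_cm"] <= 25.0).all()


def test_invalid_bias_rejected():
    with pytest.raises(ValueError, match="side_bias"):
        simulate_trajectory(side_bias=1.5, duration_s=10, seed=0)
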
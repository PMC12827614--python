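"""Tests for the NLS/MLE fitters and the recovery harness."""

import math

import numpy as np
import pandas as pd
import pytest

import adhd_dynamics as ad
from adhd_dynamics.estimate import (
    ChoiceDesign,
    DecayDesign,
    HyperactivityDesign,
    choice_log_likelihood,
    fit_decay,
    fit_discounting,
    fit_hyperactivity,
    parameter_recovery,
)
from adhd_dynamics.exceptions import (
    DataError,
    EmptyInputError,
    IdentifiabilityError,
)

CONDITIONS = [(0.0, 0.0), (1.0, 0.2), (0.3, 1.0)]


def _rel_err(est, true):
    return abs(est - true) / abs(true)


# --------------------------------------------------------------------------
# decay


def test_decay_noiseless_recovery(decay_params, session_table_factory):
    t = np.linspace(0, 30, 10)
    data = session_table_factory(decay_params, CONDITIONS, t)
    fit = fit_decay(data)
    for name in ("initial_level", "base_rate", "monotony_sensitivity",
                 "reward_sensitivity"):
        assert _rel_err(getattr(fit.estimates, name),
                        getattr(decay_params, name)) <= 1e-6
    assert fit.converged
    assert fit.n_conditions == 3
    assert fit.condition_design_rank == 3


def test_decay_two_point_rate_identity():
    """Single condition with fixed sensitivities: rate = ln(y1/y2)/(t2-t1)."""
    t1, y1, t2, y2 = 2.0, 0.8, 10.0, 0.3
    data = pd.DataFrame({"time": [t1, t2], "observed_value": [y1, y2],
                         "monotony": 0.0, "reward": 0.0})
    fit = fit_decay(data, fix_monotony_sensitivity=0.0,
                    fix_reward_sensitivity=0.0)
    expected = math.log(y1 / y2) / (t2 - t1)
    assert fit.estimates.base_rate == pytest.approx(expected, rel=1e-8)


def test_decay_identifiability_guard(decay_params, session_table_factory):
    t = np.linspace(0, 30, 10)
    two = session_table_factory(decay_params, [(0.0, 0.0), (1.0, 0.5)], t)
    with pytest.raises(IdentifiabilityError):
        fit_decay(two)
    no_reward_var = session_table_factory(
        decay_params, [(0.0, 0.0), (0.5, 0.0), (1.0, 0.0)], t
    )
    with pytest.raises(IdentifiabilityError):
        fit_decay(no_reward_var)
    # fixing the unidentifiable sensitivity makes the same design legal
    fit = fit_decay(no_reward_var, fix_reward_sensitivity=0.9)
    assert fit.converged


def test_decay_all_nonpositive_observations_rejected():
    data = pd.DataFrame({"time": [0.0, 1.0], "observed_value": [-1.0, 0.0],
                         "monotony": 0.0, "reward": 0.0})
    with pytest.raises(DataError):
        fit_decay(data, fix_monotony_sensitivity=0.0, fix_reward_sensitivity=0.0)


def test_decay_fit_dominates_parameter_grid(session_table_factory):
    """Optimizer objective beats every node of a bounded 11^4 grid."""
    true = ad.DecayParams(initial_level=1.0, base_rate=0.1,
                          monotony_sensitivity=0.6, reward_sensitivity=0.8)
    t = np.linspace(0, 30, 12)
    data = session_table_factory(true, CONDITIONS, t)
    rng = np.random.default_rng(77)
    data["observed_value"] += rng.normal(0, 0.05, len(data))
    fit = fit_decay(data)

    tt = data["time"].to_numpy()
    y = data["observed_value"].to_numpy()
    m = data["monotony"].to_numpy()
    r = data["reward"].to_numpy()

    def rss(a0, b, km, kr):
        rate = b * (1 + km * m) / (1 + kr * r)
        return float(np.sum((y - a0 * np.exp(-rate * tt)) ** 2))

    grid_a0 = np.linspace(0.5, 1.5, 11)
    grid_b = np.geomspace(0.01, 1.0, 11)
    grid_k = np.linspace(0.0, 2.0, 11)
    best_grid = min(
        rss(a0, b, km, kr)
        for a0 in grid_a0 for b in grid_b for km in grid_k for kr in grid_k
    )
    assert fit.residual_sum_of_squares <= best_grid + 1e-9


def test_decay_fit_with_piecewise_schedule(decay_params, task_schedule):
    t = np.arange(0.0, 120.0, 2.0)
    table = ad.simulate_decay_trajectory(decay_params, task_schedule, t)
    fit = fit_decay(table, schedule=task_schedule)
    for name in ("initial_level", "base_rate", "monotony_sensitivity",
                 "reward_sensitivity"):
        assert _rel_err(getattr(fit.estimates, name),
                        getattr(decay_params, name)) <= 1e-6


# --------------------------------------------------------------------------
# hyperactivity


def test_hyperactivity_single_context_noiseless_recovery():
    p = ad.HyperactivityParams(baseline=4.0, max_amplitude=2.5,
                               angular_frequency=0.35, phase=2.1)
    sched = ad.ContextSchedule((ad.Segment(0.0, 120.0, ad.ActivityContext()),))
    t = np.arange(0.0, 120.0, 0.5)
    table = ad.simulate_hyperactivity_trajectory(p, sched, t)
    fit = fit_hyperactivity(table)
    assert fit.collapsed_to_single_amplitude
    assert _rel_err(fit.estimates.baseline, 4.0) <= 1e-6
    assert _rel_err(fit.estimates.max_amplitude, 2.5) <= 1e-6
    assert _rel_err(fit.estimates.angular_frequency, 0.35) <= 1e-6
    assert _rel_err(fit.estimates.phase, 2.1) <= 1e-6


def test_hyperactivity_amplitude_ratio_identifies_sensitivity():
    """Two contexts, C in {0, 2}: k_C = (A1/A2 - 1) / C2."""
    p = ad.HyperactivityParams(baseline=3.0, max_amplitude=2.0,
                               cognitive_sensitivity=0.75,
                               angular_frequency=0.4, phase=0.5)
    sched = ad.ContextSchedule((
        ad.Segment(0.0, 60.0, ad.ActivityContext(cognitive_demand=0.0)),
        ad.Segment(60.0, 120.0, ad.ActivityContext(cognitive_demand=2.0)),
    ))
    t = np.arange(0.0, 120.0, 0.25)
    table = ad.simulate_hyperactivity_trajectory(p, sched, t)
    fit = fit_hyperactivity(table)
    a1 = ad.effective_amplitude(p, ad.ActivityContext(cognitive_demand=0.0))
    a2 = ad.effective_amplitude(p, ad.ActivityContext(cognitive_demand=2.0))
    assert (a1 / a2 - 1.0) / 2.0 == pytest.approx(0.75, rel=1e-12)
    assert _rel_err(fit.estimates.cognitive_sensitivity, 0.75) <= 1e-6
    assert not fit.collapsed_to_single_amplitude


def test_hyperactivity_full_noiseless_recovery(hyper_params, activity_schedule):
    t = np.arange(0.0, 120.0, 0.5)
    table = ad.simulate_hyperactivity_trajectory(hyper_params, activity_schedule, t)
    fit = fit_hyperactivity(table)
    for name in ("baseline", "max_amplitude", "cognitive_sensitivity",
                 "stillness_sensitivity", "calm_reinforcement_sensitivity",
                 "angular_frequency", "phase"):
        assert _rel_err(getattr(fit.estimates, name),
                        getattr(hyper_params, name)) <= 1e-6, name


def test_hyperactivity_beats_flat_model(hyper_params, activity_schedule):
    t = np.arange(0.0, 120.0, 1.0)
    table = ad.simulate_hyperactivity_trajectory(
        hyper_params, activity_schedule, t, ad.NoiseSpec("gaussian", 0.3), seed=1
    )
    fit = fit_hyperactivity(table)
    y = table["observed_value"].to_numpy()
    flat_rss = float(np.sum((y - y.mean()) ** 2))
    assert fit.residual_sum_of_squares <= flat_rss


def test_hyperactivity_short_record_flagged_unreliable():
    p = ad.HyperactivityParams(baseline=1.0, max_amplitude=0.5,
                               angular_frequency=0.05, phase=0.0)  # 126-min cycle
    sched = ad.ContextSchedule((ad.Segment(0.0, 60.0, ad.ActivityContext()),))
    t = np.arange(0.0, 60.0, 2.0)
    table = ad.simulate_hyperactivity_trajectory(p, sched, t)
    fit = fit_hyperactivity(table)
    assert fit.unreliable


# --------------------------------------------------------------------------
# discounting


def test_discounting_probability_response_is_exact():
    battery = ad.standard_choice_battery(6, 5)
    disc = ad.DiscountingParams(discount_rate=0.1)
    pol = ad.ChoicePolicy(consistency=0.2)
    tab = ad.simulate_choice_experiment(battery, disc, pol, seed=0)
    fit = fit_discounting(tab, response="true_probability")
    assert _rel_err(fit.discount_rate_estimate, 0.1) <= 1e-6
    assert _rel_err(fit.consistency_estimate, 0.2) <= 1e-6


def test_discounting_log_likelihood_matches_naive_sum():
    battery = ad.standard_choice_battery(4, 3)
    disc = ad.DiscountingParams(discount_rate=0.07)
    pol = ad.ChoicePolicy(consistency=0.3)
    tab = ad.simulate_choice_experiment(battery, disc, pol, seed=2)
    k, beta = 0.05, 0.4
    naive = 0.0
    for _, row in tab.iterrows():
        p = ad.choice_probability(
            ad.RewardProspect(amount=row.ssr_amount, delay=row.ssr_delay),
            ad.RewardProspect(amount=row.llr_amount, delay=row.llr_delay),
            ad.DiscountingParams(discount_rate=k),
            ad.ChoicePolicy(consistency=beta),
        )
        naive += row.choice * math.log(p) + (1 - row.choice) * math.log(1 - p)
    assert choice_log_likelihood(tab, k, beta) == pytest.approx(naive, abs=1e-12)


def test_discounting_fit_dominates_grid():
    """Optimum log-likelihood beats every node of a 51x51 log-spaced grid."""
    battery = ad.standard_choice_battery(6, 5)
    tab = ad.simulate_choice_experiment(
        battery * 4, ad.DiscountingParams(discount_rate=0.1),
        ad.ChoicePolicy(consistency=0.2), seed=9
    )
    fit = fit_discounting(tab)
    ks = np.geomspace(1e-4, 10, 51)
    betas = np.geomspace(1e-3, 10, 51)
    best_grid = max(
        choice_log_likelihood(tab, k, b) for k in ks for b in betas
    )
    assert fit.log_likelihood >= best_grid - 1e-9


def test_discounting_degenerate_patterns():
    battery = ad.standard_choice_battery(3, 3)
    tab = ad.simulate_choice_experiment(
        battery, ad.DiscountingParams(discount_rate=0.1),
        ad.ChoicePolicy(consistency=0.0), seed=1
    )
    all_ssr = tab.assign(choice=1)
    fit = fit_discounting(all_ssr)
    assert fit.degenerate_pattern == "all_ssr"
    assert fit.at_boundary and not fit.converged
    all_llr = tab.assign(choice=0)
    assert fit_discounting(all_llr).degenerate_pattern == "all_llr"


def test_discounting_requires_distinct_pairs_and_rows():
    with pytest.raises(EmptyInputError):
        fit_discounting(pd.DataFrame(columns=["ssr_amount"]))
    one_pair = ad.simulate_choice_experiment(
        ad.standard_choice_battery(1, 1) * 5,
        ad.DiscountingParams(discount_rate=0.1),
        ad.ChoicePolicy(consistency=0.2), seed=0,
    )
    with pytest.raises(IdentifiabilityError):
        fit_discounting(one_pair)


def test_discounting_log_likelihood_nonpositive_for_binary_choices():
    tab = ad.simulate_choice_experiment(
        ad.standard_choice_battery(5, 4),
        ad.DiscountingParams(discount_rate=0.05),
        ad.ChoicePolicy(consistency=0.5), seed=4,
    )
    fit = fit_discounting(tab)
    assert fit.log_likelihood <= 0.0


# --------------------------------------------------------------------------
# parameter recovery harness


def test_noiseless_recovery_report_is_exact(decay_params, task_schedule):
    design = DecayDesign(task_schedule, tuple(np.arange(0.0, 120.0, 2.0)))
    report = parameter_recovery(decay_params, design, n_replicates=3, seed=5)
    assert report.n_failed == 0
    assert (report.table["relative_bias"].abs() <= 1e-6).all()
    assert (report.table["rmse"] >= report.table["bias"].abs() - 1e-15).all()


def test_recovery_report_deterministic(decay_params, task_schedule):
    design = DecayDesign(task_schedule, tuple(np.arange(0.0, 120.0, 2.0)),
                         ad.NoiseSpec("gaussian", 0.05))
    a = parameter_recovery(decay_params, design, n_replicates=5, seed=42)
    b = parameter_recovery(decay_params, design, n_replicates=5, seed=42)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_recovery_rmse_shrinks_with_sample_size(decay_params, task_schedule):
    """RMSE of the base rate decreases as the grid grows 50 -> 200 -> 800."""
    rmses = []
    for n in (50, 200, 800):
        times = tuple(np.linspace(0.0, 119.0, n))
        design = DecayDesign(task_schedule, times, ad.NoiseSpec("gaussian", 0.05))
        rep = parameter_recovery(decay_params, design, n_replicates=20, seed=8)
        row = rep.table.set_index("parameter").loc["base_rate"]
        rmses.append(row["rmse"])
    assert rmses[0] > rmses[1] > rmses[2]


def test_choice_recovery_with_probability_response():
    design = ChoiceDesign(tuple(ad.standard_choice_battery(6, 5)),
                          response="true_probability")
    true = (ad.DiscountingParams(discount_rate=0.1),
            ad.ChoicePolicy(consistency=0.2))
    report = parameter_recovery(true, design, n_replicates=2, seed=3)
    assert (report.table["relative_bias"].abs() <= 1e-6).all()


def test_hyperactivity_recovery_wraps_phase(activity_schedule):
    p = ad.HyperactivityParams(baseline=5.0, max_amplitude=3.0,
                               cognitive_sensitivity=0.8,
                               stillness_sensitivity=0.4,
                               calm_reinforcement_sensitivity=0.6,
                               angular_frequency=0.21, phase=6.28)  # near wrap
    design = HyperactivityDesign(activity_schedule,
                                 tuple(np.arange(0.0, 120.0, 0.5)))
    report = parameter_recovery(p, design, n_replicates=2, seed=6)
    phase_row = report.table.set_index("parameter").loc["phase"]
    assert abs(phase_row["bias"]) <= 1e-6
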
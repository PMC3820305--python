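"""Beta-binomial predictive machinery against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, optimize, stats

from stemdiff.bayes import (
    DEFAULT_PRIOR,
    BetaState,
    TrialState,
    credible_interval,
    monitor,
    posterior_update,
    predictive_pmf,
    prior_sensitivity,
    prob_goal,
)


def test_posterior_update_reproduces_printed_shapes():
    # s = 5 successes now, t = 3 future successes, N = 20 total:
    # alpha* = s + t + alpha = 9, beta* = N - s - t + beta = 13
    prior = BetaState(1.0, 1.0)
    s, t, N = 5, 3, 20
    post = posterior_update(prior, s + t, N - s - t)
    assert post == BetaState(9.0, 13.0)


def test_posterior_update_identity_and_additivity():
    prior = BetaState(1.0, 1.0)
    assert posterior_update(prior, 0, 0) == prior
    seq = posterior_update(posterior_update(prior, 5, 2), 3, 4)
    assert seq == posterior_update(prior, 8, 6)
    with pytest.raises(ValueError):
        posterior_update(prior, -1, 0)


def test_uniform_prior_no_data_predictive_is_uniform():
    pmf = predictive_pmf(BetaState(1, 1), TrialState(10, 0, 0))
    assert np.allclose(pmf.probabilities, 1.0 / 11.0, atol=1e-12)


def test_no_remaining_cells_is_a_point_mass_at_zero():
    pmf = predictive_pmf(BetaState(2, 3), TrialState(12, 12, 7))
    assert pmf.support.tolist() == [0]
    assert pmf.probabilities[0] == pytest.approx(1.0, abs=1e-12)


@given(
    alpha=st.sampled_from([0.5, 1.0, 2.0, 5.0]),
    beta=st.sampled_from([0.5, 1.0, 2.0, 5.0]),
    N=st.integers(1, 50),
    data=st.data(),
)
def test_predictive_pmf_normalises_and_matches_scipy(alpha, beta, N, data):
    n = data.draw(st.integers(0, N))
    s = data.draw(st.integers(0, n))
    pmf = predictive_pmf(BetaState(alpha, beta), TrialState(N, n, s))
    assert pmf.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
    assert (pmf.probabilities >= 0).all()
    # independent oracle: scipy's beta-binomial over the remaining draws
    oracle = stats.betabinom.pmf(pmf.support, N - n, alpha + s, beta + n - s)
    assert np.allclose(pmf.probabilities, oracle, atol=1e-12)
    # law of total expectation
    mean = (pmf.support * pmf.probabilities).sum()
    expected = (N - n) * (alpha + s) / (alpha + beta + n)
    assert mean == pytest.approx(expected, abs=1e-9)


def test_predictive_pmf_matches_monte_carlo(rng):
    alpha, beta, N, n, s = 2.0, 3.0, 30, 10, 4
    pmf = predictive_pmf(BetaState(alpha, beta), TrialState(N, n, s))
    draws = 100_000
    p_star = rng.beta(alpha + s, beta + n - s, size=draws)
    t_draws = rng.binomial(N - n, p_star)
    for t in pmf.support:
        emp = (t_draws == t).mean()
        se = np.sqrt(max(pmf.probabilities[t], 1e-12) / draws)
        assert abs(emp - pmf.probabilities[t]) < 3.5 * se + 1e-4


def test_prob_goal_edges_and_enumeration_oracle():
    prior = BetaState(1, 1)
    trial = TrialState(20, 8, 5)
    assert prob_goal(prior, trial, 5) == 1.0
    assert prob_goal(prior, trial, 0) == 1.0
    # goal 17 needs every one of the 12 remaining cells to succeed
    assert prob_goal(prior, trial, 17) == pytest.approx(
        stats.betabinom.pmf(12, 12, 6, 4), abs=1e-12
    )
    assert prob_goal(prior, trial, 20) == 0.0
    # goal - s > N - n is unreachable only when goal > N, which errors;
    # the zero branch needs s lower than n - (N - goal)
    assert prob_goal(prior, TrialState(20, 19, 0), 2) == 0.0
    with pytest.raises(ValueError):
        prob_goal(prior, trial, 21)
    for goal in range(0, 21):
        oracle = float(stats.betabinom.sf(goal - 5 - 1, 12, 6, 4)) if goal > 5 else 1.0
        assert prob_goal(prior, trial, goal) == pytest.approx(oracle, abs=1e-10)


def test_prob_goal_monotone_in_goal_and_successes():
    prior = BetaState(1, 1)
    vals = [prob_goal(prior, TrialState(30, 10, 4), g) for g in range(31)]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    by_s = [prob_goal(prior, TrialState(30, 10, s), 15) for s in range(11)]
    assert all(b >= a - 1e-12 for a, b in zip(by_s, by_s[1:]))


def test_monitor_stops_at_first_threshold_crossing():
    prior = BetaState(1, 1)
    # certain success / certain failure stop immediately
    sup = monitor([TrialState(10, 10, 10)], prior, goal=5)
    assert [d.action for d in sup] == ["stop_superiority"]
    fut = monitor([TrialState(10, 9, 0)], prior, goal=9)
    assert [d.action for d in fut] == ["stop_futility"]

    # a trajectory straddling the thresholds: hand-enumerated actions
    looks = [TrialState(20, 5, 3), TrialState(20, 12, 9), TrialState(20, 16, 14)]
    decisions = monitor(looks, prior, goal=15, superiority=0.95, futility=0.05)
    expected_probs = [prob_goal(prior, lk, 15) for lk in looks]
    assert expected_probs[0] > 0.05 and expected_probs[0] < 0.95
    assert [d.prob_success for d in decisions] == expected_probs[: len(decisions)]
    actions = [d.action for d in decisions]
    assert actions[:-1] == ["continue"] * (len(actions) - 1)
    assert actions[-1] in {"stop_superiority", "continue"}

    with pytest.raises(ValueError, match="inconsistent"):
        monitor([TrialState(20, 10, 5), TrialState(20, 12, 4)], prior, goal=10)


def test_credible_interval_uniform_and_quadrature_oracle():
    assert credible_interval(BetaState(1, 1), 0.95) == pytest.approx(
        (0.025, 0.975), abs=1e-12
    )

    post = BetaState(9, 13)
    lo, hi = credible_interval(post, 0.95)

    def cdf(x):
        val, _ = integrate.quad(lambda u: stats.beta.pdf(u, 9, 13), 0.0, x)
        return val

    lo_oracle = optimize.brentq(lambda x: cdf(x) - 0.025, 1e-9, 1 - 1e-9, xtol=1e-12)
    hi_oracle = optimize.brentq(lambda x: cdf(x) - 0.975, 1e-9, 1 - 1e-9, xtol=1e-12)
    assert lo == pytest.approx(lo_oracle, abs=1e-6)
    assert hi == pytest.approx(hi_oracle, abs=1e-6)


def test_credible_interval_width_shrinks_with_information():
    widths = []
    for scale in (1, 4, 16, 64):
        lo, hi = credible_interval(BetaState(2 * scale, 3 * scale), 0.95)
        widths.append(hi - lo)
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_prior_sensitivity_matches_closed_form():
    trial = TrialState(20, 8, 5)
    grid = [BetaState(0.5, 0.5), BetaState(1, 1), BetaState(2, 2)]
    report = prior_sensitivity(trial, grid, goal=10)
    means = [(a + 5) / (a + b + 8) for a, b in grid]
    assert report["divergence"] == pytest.approx(max(means) - min(means), abs=1e-12)

    # no data: posterior means equal prior means
    empty = prior_sensitivity(TrialState(20, 0, 0),
                              [BetaState(1, 1), BetaState(1, 3)], goal=5)
    assert empty["rows"][0]["posterior_mean"] == pytest.approx(0.5)
    assert empty["rows"][1]["posterior_mean"] == pytest.approx(0.25)

    # large n swamps any prior
    big = prior_sensitivity(TrialState(20_000, 10_000, 6_000), grid, goal=10_000)
    assert big["divergence"] <= 1e-3
    assert not big["prior_dominated"]

    with pytest.raises(ValueError):
        prior_sensitivity(trial, [], goal=5)


def test_default_prior_is_flat():
    assert DEFAULT_PRIOR == BetaState(1.0, 1.0)
    with pytest.raises(ValueError):
        BetaState(0.0, 1.0).validate()
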
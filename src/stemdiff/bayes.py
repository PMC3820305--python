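"""Conjugate beta-binomial machinery for sequential monitoring.

A differentiation experiment is monitored like a single-arm clinical trial
with a binary endpoint: of N cells that can differentiate, n have been
assayed so far and s of those have differentiated. With a Beta(alpha, beta)
prior on the event rate, the posterior after (s, n) is
Beta(alpha + s, beta + n - s), and the number T of further successes among
the N - n remaining cells follows the beta-binomial predictive

    P(T = t | s) = C(N-n, t) * B(alpha+s+t, beta+N-s-t) / B(alpha+s, beta+n-s),

for t in 0..N-n. Interim looks stop the experiment early when the predicted
probability of reaching the goal crosses a superiority or futility
threshold. The default prior is the non-informative Beta(1, 1); a
prior-sensitivity sweep flags prior-dominated conclusions.

All beta-function arithmetic is done in log space so states up to N ~ 1e6
do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import betaln, gammaln

#: Default non-informative prior.
DEFAULT_PRIOR_ALPHA = 1.0
DEFAULT_PRIOR_BETA = 1.0

#: Default stopping thresholds on the predicted probability of success.
DEFAULT_SUPERIORITY = 0.95
DEFAULT_FUTILITY = 0.05


class BetaState(NamedTuple):
    """Shape parameters of a beta prior or posterior."""

    alpha: float
    beta: float

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def validate(self) -> "BetaState":
        if not (self.alpha > 0 and self.beta > 0
                and np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError(f"beta shapes must be positive finite, got {self}")
        return self


DEFAULT_PRIOR = BetaState(DEFAULT_PRIOR_ALPHA, DEFAULT_PRIOR_BETA)


class TrialState(NamedTuple):
    """Bookkeeping of one interim look: N total, n assayed, s successes."""

    N: int
    n: int
    s: int

    def validate(self) -> "TrialState":
        if not 0 <= self.s <= self.n <= self.N:
            raise ValueError(f"need 0 <= s <= n <= N, got {self}")
        return self


@dataclass(frozen=True)
class PredictivePMF:
    """Predictive mass over t future successes among the remaining cells."""

    support: np.ndarray
    probabilities: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.support * self.probabilities))


@dataclass(frozen=True)
class MonitoringDecision:
    look_index: int
    prob_success: float
    action: str  # continue | stop_superiority | stop_futility


def posterior_update(prior: BetaState, successes: int, failures: int) -> BetaState:
    """Conjugate update: Beta(alpha + successes, beta + failures).

    With successes = s + t and failures = N - s - t this reproduces the
    posterior shapes alpha* = s + t + alpha, beta* = N - s - t + beta after
    all N cells have been observed.
    """
    BetaState(*prior).validate()
    if successes < 0 or failures < 0:
        raise ValueError("counts must be non-negative")
    return BetaState(prior.alpha + successes, prior.beta + failures)


def predictive_pmf(prior: BetaState, trial: TrialState) -> PredictivePMF:
    """Beta-binomial predictive for future successes (log-space evaluation)."""
    prior = BetaState(*prior).validate()
    trial = TrialState(*trial).validate()
    m = trial.N - trial.n
    t = np.arange(m + 1)
    a = prior.alpha + trial.s
    b = prior.beta + trial.n - trial.s
    logp = (
        gammaln(m + 1) - gammaln(t + 1) - gammaln(m - t + 1)
        + betaln(a + t, b + m - t) - betaln(a, b)
    )
    return PredictivePMF(support=t, probabilities=np.exp(logp))


def prob_goal(prior: BetaState, trial: TrialState, goal: int) -> float:
    """Predicted probability of ending with at least ``goal`` total successes."""
    trial = TrialState(*trial).validate()
    if goal > trial.N:
        raise ValueError(f"goal {goal} exceeds N={trial.N}")
    need = goal - trial.s
    if need <= 0:
        return 1.0
    if need > trial.N - trial.n:
        return 0.0
    pmf = predictive_pmf(prior, trial)
    return float(min(1.0, max(0.0, pmf.probabilities[pmf.support >= need].sum())))


def monitor(looks: Sequence[TrialState], prior: BetaState = DEFAULT_PRIOR,
            goal: int = 0, superiority: float = DEFAULT_SUPERIORITY,
            futility: float = DEFAULT_FUTILITY) -> list[MonitoringDecision]:
    """Sequential interim monitoring with early stopping.

    Evaluates looks in order; the first crossing of a threshold stops the
    experiment (``stop_superiority`` if the predicted success probability is
    at least the superiority threshold, ``stop_futility`` if at most the
    futility threshold) and later looks are not evaluated.
    """
    if not 0 < futility < superiority < 1:
        raise ValueError("need 0 < futility < superiority < 1")
    looks = [TrialState(*lk).validate() for lk in looks]
    for prev, cur in zip(looks, looks[1:]):
        if cur.n < prev.n or cur.s < prev.s or cur.N != prev.N:
            raise ValueError(f"inconsistent looks: {prev} -> {cur}")
    decisions: list[MonitoringDecision] = []
    for i, lk in enumerate(looks):
        p = prob_goal(prior, lk, goal)
        if p >= superiority:
            action = "stop_superiority"
        elif p <= futility:
            action = "stop_futility"
        else:
            action = "continue"
        decisions.append(MonitoringDecision(i, p, action))
        if action != "continue":
            break
    return decisions


def credible_interval(post: BetaState, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval for the event rate from beta quantiles."""
    post = BetaState(*post).validate()
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0,1), got {level}")
    tail = (1.0 - level) / 2.0
    lo = stats.beta.ppf(tail, post.alpha, post.beta)
    hi = stats.beta.ppf(1.0 - tail, post.alpha, post.beta)
    return float(lo), float(hi)


def prior_sensitivity(trial: TrialState, priors: Iterable[BetaState],
                      goal: int = 0, level: float = 0.95,
                      tolerance: float = 0.1) -> dict:
    """Sweep a grid of priors and report how much they move the answer.

    For each prior: posterior mean, equal-tailed credible interval and the
    predicted probability of reaching the goal. The report's ``divergence``
    is the largest pairwise gap between posterior means; the analysis is
    flagged ``prior_dominated`` when it exceeds ``tolerance``.
    """
    priors = [BetaState(*p).validate() for p in priors]
    if not priors:
        raise ValueError("prior grid is empty")
    trial = TrialState(*trial).validate()
    rows = []
    for p in priors:
        post = posterior_update(p, trial.s, trial.n - trial.s)
        lo, hi = credible_interval(post, level)
        rows.append(
            {
                "prior_alpha": p.alpha,
                "prior_beta": p.beta,
                "posterior_mean": post.mean(),
                "ci_lower": lo,
                "ci_upper": hi,
                "prob_goal": prob_goal(p, trial, goal),
            }
        )
    means = [r["posterior_mean"] for r in rows]
    divergence = max(means) - min(means)
    return {
        "rows": rows,
        "divergence": divergence,
        "prior_dominated": divergence > tolerance,
        "tolerance": tolerance,
    }
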
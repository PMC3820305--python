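"""Time-to-commitment survival analysis with competing risks.

The event of interest is commitment to the neuroectodermal fate (first
Sox3-promoter-GFP expression); cell death (PI-positive) and commitment to a
non-neural fate are competing events, and cells with no event by the end of
the culture are administratively censored. Kaplan-Meier curves and the
log-rank comparison come from lifelines; the Aalen-Johansen cumulative
incidence functions are accumulated directly from the all-cause
product-limit estimator so that S(t) + sum_k CIF_k(t) = 1 holds exactly at
every event time. Ties at identical times follow the standard convention
(events precede censorings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

#: Recognised event codes (plus "censored").
EVENT_TYPES = ("neuroectoderm_commit", "death", "other_fate")
EVENT_OF_INTEREST = "neuroectoderm_commit"


@dataclass
class SurvivalEstimate:
    """Step functions evaluated at the sorted observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    cif: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.event_times, "survival": self.survival,
                            "at_risk": self.at_risk})
        for name, values in self.cif.items():
            out[f"cif_{name}"] = values
        return out


@dataclass
class GroupComparison:
    """Log-rank comparison of the event of interest between two groups."""

    statistic: float
    p_value: float
    medians: dict[str, float]
    n_per_group: dict[str, int]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"survival records missing columns: {sorted(missing)}")
    if records.empty:
        raise ValueError("no survival records")
    if (records["time"] < 0).any():
        raise ValueError("negative event times")
    return records


def km_estimate(records: pd.DataFrame, event_of_interest: str = EVENT_OF_INTEREST
                ) -> SurvivalEstimate:
    """Product-limit survival for one event type; other events are censored."""
    records = _validate(records)
    observed = (records["event"] == event_of_interest).to_numpy().astype(int)
    times = records["time"].to_numpy(dtype=float)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)

    if observed.sum() == 0:
        grid = np.array([float(times.max())])
    else:
        grid = np.unique(times[observed == 1])
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in grid])
    return SurvivalEstimate(event_times=grid, survival=surv, at_risk=at_risk)


def cif_estimate(records: pd.DataFrame) -> SurvivalEstimate:
    """Aalen-Johansen cumulative incidence for every competing event.

    CIF_k jumps by S(t-) * d_k / n at each event time, where S is the
    all-cause Kaplan-Meier survival; conservation S + sum CIF = 1 holds by
    construction.
    """
    records = _validate(records)
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy()
    kinds = [k for k in EVENT_TYPES if (events == k).any()]
    any_event = events != "censored"
    if not any_event.any():
        grid = np.array([float(times.max())])
        return SurvivalEstimate(grid, np.ones(1), np.array([len(records)]),
                                {k: np.zeros(1) for k in kinds})

    grid = np.unique(times[any_event])
    surv = np.empty(grid.size)
    at_risk = np.empty(grid.size, dtype=int)
    cif = {k: np.zeros(grid.size) for k in kinds}
    s_prev = 1.0
    running = {k: 0.0 for k in kinds}
    for j, t in enumerate(grid):
        n_risk = int((times >= t).sum())
        at_risk[j] = n_risk
        d_all = int((any_event & (times == t)).sum())
        for k in kinds:
            d_k = int(((events == k) & (times == t)).sum())
            running[k] += s_prev * d_k / n_risk
            cif[k][j] = running[k]
        s_prev *= 1.0 - d_all / n_risk
        surv[j] = s_prev
    return SurvivalEstimate(grid, surv, at_risk, cif)


def compare_groups(records: pd.DataFrame,
                   event_of_interest: str = EVENT_OF_INTEREST,
                   group_col: str = "group") -> GroupComparison:
    """Two-group log-rank test on the event of interest (others censored)."""
    records = _validate(records)
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    observed = (records["event"] == event_of_interest).astype(int)
    mask = records[group_col] == groups[0]

    res = logrank_test(
        records.loc[mask, "time"], records.loc[~mask, "time"],
        event_observed_A=observed[mask], event_observed_B=observed[~mask],
    )
    medians = {}
    n_per_group = {}
    for g in groups:
        sel = records[group_col] == g
        kmf = KaplanMeierFitter().fit(records.loc[sel, "time"], observed[sel])
        medians[g] = float(kmf.median_survival_time_)
        n_per_group[g] = int(sel.sum())
    return GroupComparison(float(res.test_statistic), float(res.p_value),
                           medians, n_per_group)


def plot_survival(estimate: SurvivalEstimate, ax=None):
    """Step plot of the survival curve and any cumulative incidence curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(estimate.event_times, estimate.survival, where="post",
            label="survival")
    for name, values in estimate.cif.items():
        ax.step(estimate.event_times, values, where="post", label=f"CIF {name}")
    ax.set_xlabel("days of differentiation")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
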
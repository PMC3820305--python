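"""Synthetic differentiating embryoid-body populations.

The generator emulates the statistical structure assumed by the design
framework: each cell is assigned a germ-layer fate; commitment days are
drawn from per-fate truncated Normal distributions (whose superposition
yields the sigmoid cumulative-differentiation curve); endoderm and mesoderm
cells pass through a transitional mesendoderm state; a sub-fraction of
ectodermal cells progresses to the Sox3-only neuroectoderm pattern after a
lag (the Sox3-promoter-GFP onset); a residual fraction of cells never
commits (Nanog+ cells persisting at day 10); death is a competing risk with
a constant per-day hazard. A dominant-negative STAT3 (STAT3beta) condition
reduces the ectoderm fraction and delays ectoderm commitment.

Populations are assayed as flow-cytometry-style event tables: at each
sampling time and replicate a fixed number of cells is drawn and its truth
marker profile is recorded with independent per-marker flip noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markers import CANONICAL_PROFILES, MARKER_COLUMNS, MarkerProfile

GERM_LAYERS = ("endoderm", "mesoderm", "ectoderm")

#: Event-table column schema (one row per sampled cell per assay time).
EVENT_COLUMNS = ("cell_id", "time_days", "replicate", "condition", "viability") + MARKER_COLUMNS


class ConfigError(ValueError):
    """Raised for invalid population configurations."""


@dataclass
class PopulationConfig:
    """Truth parameters of one simulated embryoid-body population.

    Defaults encode the hypothesised study conditions: endoderm commitment
    peaking at day 3 and mesoderm/ectoderm at day 7 over a 10-day horizon,
    with ~5% of cells remaining Nanog+ at the end of the time course.
    """

    n_cells: int = 5000
    horizon_days: float = 10.0
    fate_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"endoderm": 0.30, "mesoderm": 0.35, "ectoderm": 0.35}
    )
    commitment_mean: Mapping[str, float] = field(
        default_factory=lambda: {"endoderm": 3.0, "mesoderm": 7.0, "ectoderm": 7.0}
    )
    commitment_sd: Mapping[str, float] = field(
        default_factory=lambda: {"endoderm": 1.0, "mesoderm": 1.0, "ectoderm": 1.0}
    )
    mesendoderm_lead: float = 1.0
    residual_nanog_fraction: float = 0.05
    neuro_fraction: float = 0.5
    neuro_lag: float = 1.0
    flip_noise: float = 0.02
    death_hazard: float = 0.02
    condition: str = "wt"
    stat3b_ecto_factor: float = 0.5
    stat3b_ecto_delay: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if self.condition not in ("wt", "stat3b"):
            raise ConfigError(f"unknown condition {self.condition!r}")
        total = sum(self.fate_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"fate_fractions must sum to 1, got {total}")
        for name, frac in self.fate_fractions.items():
            if name not in GERM_LAYERS:
                raise ConfigError(f"unknown fate {name!r} in fate_fractions")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fate fraction out of [0,1]: {name}={frac}")
        for fate, sd in self.commitment_sd.items():
            if sd < 0:
                raise ConfigError(f"commitment_sd must be >= 0, got {fate}={sd}")
        for name in ("residual_nanog_fraction", "neuro_fraction", "flip_noise",
                     "death_hazard", "stat3b_ecto_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1], got {v}")

    def effective_fractions(self) -> dict[str, float]:
        """Fate fractions after the condition effect.

        Under stat3b the ectoderm fraction is multiplied by
        ``stat3b_ecto_factor`` and the excess mass is reassigned to the
        other fates proportionally to their wild-type fractions.
        """
        fracs = {f: float(self.fate_fractions.get(f, 0.0)) for f in GERM_LAYERS}
        if self.condition == "stat3b":
            excess = fracs["ectoderm"] * (1.0 - self.stat3b_ecto_factor)
            fracs["ectoderm"] *= self.stat3b_ecto_factor
            others = {k: v for k, v in fracs.items() if k != "ectoderm"}
            denom = sum(others.values())
            for k in others:
                fracs[k] += excess * others[k] / denom if denom > 0 else excess / len(others)
        return fracs

    def effective_mean(self, fate: str) -> float:
        mean = float(self.commitment_mean[fate])
        if self.condition == "stat3b" and fate == "ectoderm":
            mean += self.stat3b_ecto_delay
        return mean

    def replace(self, **kwargs) -> "PopulationConfig":
        return dataclasses.replace(self, **kwargs)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, low, high))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_population(config: PopulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one population of cell truth records.

    Returns a DataFrame with one row per cell: ``cell_id``, ``true_fate``,
    ``commitment_day``, ``mesendoderm_entry_day``, ``death_day``,
    ``gfp_onset_day`` (neuroectoderm cells only) and ``condition``.
    Uncommitted (residual) cells carry NaN commitment days.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    horizon = config.horizon_days

    fracs = config.effective_fractions()
    residual = rng.random(n) < config.residual_nanog_fraction
    fates = np.array(
        rng.choice(GERM_LAYERS, size=n, p=[fracs[f] for f in GERM_LAYERS]),
        dtype=object,
    )
    fates[residual] = "undifferentiated"

    commitment = np.full(n, np.nan)
    for fate in GERM_LAYERS:
        idx = np.flatnonzero(fates == fate)
        if idx.size:
            commitment[idx] = _truncnorm(
                rng, config.effective_mean(fate),
                float(config.commitment_sd[fate]), 0.0, horizon, idx.size,
            )

    entry = np.full(n, np.nan)
    transitional = np.isin(fates, ("endoderm", "mesoderm"))
    entry[transitional] = np.clip(commitment[transitional] - config.mesendoderm_lead, 0.0, None)

    # Ectoderm sub-fraction progressing to the Sox3-only neuroectoderm state.
    gfp = np.full(n, np.nan)
    ecto = np.flatnonzero(fates == "ectoderm")
    neuro = ecto[rng.random(ecto.size) < config.neuro_fraction]
    fates[neuro] = "neuroectoderm"
    gfp[neuro] = commitment[neuro] + config.neuro_lag

    # Constant per-day death hazard p -> exponential event times with
    # P(T > d) = (1 - p)^d; hazard 0 means no deaths.
    if config.death_hazard > 0:
        rate = -math.log1p(-config.death_hazard)
        death = rng.exponential(scale=1.0 / rate, size=n)
        death[death > horizon] = np.nan
    else:
        death = np.full(n, np.nan)

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "true_fate": fates,
            "commitment_day": commitment,
            "mesendoderm_entry_day": entry,
            "death_day": death,
            "gfp_onset_day": gfp,
            "condition": config.condition,
        }
    )


def _truth_matrix(population: pd.DataFrame, time: float) -> np.ndarray:
    """Noise-free (n_cells, 7) marker matrix of the population at ``time``.

    Dead cells are frozen in the marker state they held at death.
    """
    n = len(population)
    fate = population["true_fate"].to_numpy()
    commit = population["commitment_day"].to_numpy()
    entry = population["mesendoderm_entry_day"].to_numpy()
    death = population["death_day"].to_numpy()
    gfp = population["gfp_onset_day"].to_numpy()

    t_eff = np.full(n, float(time))
    dead = ~np.isnan(death) & (death <= time)
    t_eff[dead] = death[dead]

    out = np.tile(np.array(CANONICAL_PROFILES["undifferentiated"], dtype=np.uint8), (n, 1))
    committed = ~np.isnan(commit) & (commit <= t_eff)
    in_mesendo = ~np.isnan(entry) & (entry <= t_eff) & ~committed

    out[in_mesendo] = np.array(CANONICAL_PROFILES["mesendoderm"], dtype=np.uint8)
    for f in ("endoderm", "mesoderm", "ectoderm"):
        mask = committed & (fate == f)
        out[mask] = np.array(CANONICAL_PROFILES[f], dtype=np.uint8)
    # Neuroectoderm cells express the ectoderm pattern from commitment and
    # switch to Sox3-only at GFP onset.
    neuro = fate == "neuroectoderm"
    pre = committed & neuro & ~(~np.isnan(gfp) & (gfp <= t_eff))
    post = committed & neuro & ~np.isnan(gfp) & (gfp <= t_eff)
    out[pre] = np.array(CANONICAL_PROFILES["ectoderm"], dtype=np.uint8)
    out[post] = np.array(CANONICAL_PROFILES["neuroectoderm"], dtype=np.uint8)
    return out


def marker_state(cell: pd.Series | Mapping, time: float) -> MarkerProfile:
    """Noise-free marker profile of one cell truth record at ``time``."""
    row = pd.DataFrame([dict(cell)])
    return MarkerProfile(*_truth_matrix(row, time)[0].tolist())


def assay(population: pd.DataFrame, times: Sequence[float], replicates: int,
          sample_size: int, flip_noise: float | None = None,
          rng: np.random.Generator | None = None,
          seed: int | None = None) -> pd.DataFrame:
    """Sample the population as a noisy flow-cytometry-style event table.

    Per (time, replicate) a fresh draw of ``sample_size`` cells without
    replacement is taken; each marker call is independently inverted with
    probability ``flip_noise``. Dead cells appear with ``viability='dead'``
    (the PI-staining analogue) and markers frozen at death.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if flip_noise is None:
        flip_noise = 0.0
    n = len(population)
    death = population["death_day"].to_numpy()
    condition = population["condition"].iloc[0] if n else "wt"

    blocks = []
    for t in times:
        alive = np.isnan(death) | (death > t)
        if sample_size > int(alive.sum()):
            raise ValueError(
                f"sample_size {sample_size} exceeds {int(alive.sum())} alive cells at day {t}"
            )
        truth = _truth_matrix(population, t)
        for rep in range(replicates):
            idx = rng.choice(n, size=sample_size, replace=False)
            profiles = truth[idx].copy()
            if flip_noise > 0:
                flips = rng.random(profiles.shape) < flip_noise
                profiles ^= flips.astype(np.uint8)
            block = pd.DataFrame(profiles, columns=list(MARKER_COLUMNS))
            block.insert(0, "cell_id", population["cell_id"].to_numpy()[idx])
            block.insert(1, "time_days", float(t))
            block.insert(2, "replicate", rep)
            block.insert(3, "condition", condition)
            block.insert(4, "viability", np.where(alive[idx], "alive", "dead"))
            blocks.append(block)
    if not blocks:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    return pd.concat(blocks, ignore_index=True)


def _fate_labels(fate: str) -> tuple[str, ...]:
    # Neuroectoderm is a progression of committed ectoderm, so ectodermal
    # commitment counts include both patterns.
    return ("ectoderm", "neuroectoderm") if fate == "ectoderm" else (fate,)


def differentiation_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Per (time, replicate) totals of assayed and differentiated live cells.

    Differentiated means Nanog-negative. Dead cells are gated out, as a
    viability stain would.
    """
    live = events[events["viability"] == "alive"]
    grouped = live.groupby(["time_days", "replicate"])
    out = grouped.agg(
        n_assayed=("nanog", "size"),
        n_differentiated=("nanog", lambda s: int((s == 0).sum())),
    ).reset_index()
    return out.rename(columns={"time_days": "time"})


def fate_counts(events: pd.DataFrame, fate: str) -> pd.DataFrame:
    """Per (time, replicate) counts of live cells classified as ``fate``."""
    from .markers import classify_table

    live = events[events["viability"] == "alive"].copy()
    live["fate"] = classify_table(live)
    labels = _fate_labels(fate)
    live["hit"] = live["fate"].isin(labels).astype(int)
    out = (
        live.groupby(["time_days", "replicate"])["hit"].sum().reset_index(name="count")
    )
    return out.rename(columns={"time_days": "time"})


def new_fate_counts(events: pd.DataFrame, fate: str) -> pd.DataFrame:
    """Per-interval newly committed counts for one fate (time, count).

    First differences of the replicate-mean cumulative pattern counts,
    clipped at zero; each differenced count estimates commitments during
    (t_{i-1}, t_i] and is reported at the interval midpoint so the peak of
    the resulting rate curve is unbiased. This is the observable estimate
    of the commitment-rate curve whose peak seeds the Bayesian iteration.
    """
    cum = fate_counts(events, fate).groupby("time")["count"].mean().sort_index()
    t = cum.index.to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two assay times to difference")
    diffs = np.diff(cum.to_numpy()).clip(min=0.0)
    mids = 0.5 * (t[1:] + t[:-1])
    return pd.DataFrame({"time": mids, "count": diffs})


def survival_records(population: pd.DataFrame,
                     horizon: float = 10.0) -> pd.DataFrame:
    """Derive time-to-event records from a population truth table.

    The event of interest is commitment to the neuroectodermal fate (first
    Sox3-promoter-GFP expression); competing events are death and commitment
    to any other fate. Cells with no event by the horizon are
    administratively censored.
    """
    n = len(population)
    fate = population["true_fate"].to_numpy()
    commit = population["commitment_day"].to_numpy()
    death = population["death_day"].to_numpy()
    gfp = population["gfp_onset_day"].to_numpy()

    cand_times = np.full((n, 3), np.inf)
    neuro = fate == "neuroectoderm"
    cand_times[neuro, 0] = gfp[neuro]
    cand_times[~np.isnan(death), 1] = death[~np.isnan(death)]
    other = ~neuro & ~np.isnan(commit)
    cand_times[other, 2] = commit[other]

    which = np.argmin(cand_times, axis=1)
    tmin = cand_times[np.arange(n), which]
    labels = np.array(["neuroectoderm_commit", "death", "other_fate"], dtype=object)
    event = labels[which]
    censored = tmin > horizon
    event[censored] = "censored"
    time = np.where(censored, horizon, tmin)

    return pd.DataFrame(
        {
            "subject_id": population["cell_id"].to_numpy(),
            "time": time,
            "event": event,
            "group": population["condition"].to_numpy(),
        }
    )
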
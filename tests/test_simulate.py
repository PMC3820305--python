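"""Synthetic-population generator: truth structure, assays, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from stemdiff.markers import MarkerProfile, classify_table
from stemdiff.simulate import (
    ConfigError,
    PopulationConfig,
    assay,
    differentiation_counts,
    marker_state,
    new_fate_counts,
    simulate_population,
    survival_records,
)


def test_invalid_configs_are_rejected():
    with pytest.raises(ConfigError):
        PopulationConfig(fate_fractions={"endoderm": 0.5, "mesoderm": 0.2})
    with pytest.raises(ConfigError):
        PopulationConfig(commitment_sd={"endoderm": -1.0})
    with pytest.raises(ConfigError):
        PopulationConfig(flip_noise=1.5)


def test_population_conserves_cells(wt_population):
    assert len(wt_population) == 2000
    assert wt_population["true_fate"].notna().all()


def test_degenerate_all_ectoderm_commits_on_the_mean_day():
    cfg = PopulationConfig(
        n_cells=200,
        fate_fractions={"ectoderm": 1.0},
        commitment_mean={"ectoderm": 7.0},
        commitment_sd={"ectoderm": 0.0},
        residual_nanog_fraction=0.0,
        death_hazard=0.0,
        seed=3,
    )
    pop = simulate_population(cfg)
    assert np.allclose(pop["commitment_day"], 7.0)
    assert set(pop["true_fate"]) <= {"ectoderm", "neuroectoderm"}


def test_seeded_runs_are_identical():
    cfg = PopulationConfig(n_cells=300, seed=99)
    a, b = simulate_population(cfg), simulate_population(cfg)
    pd.testing.assert_frame_equal(a, b)
    ea = assay(a, times=[2.0, 5.0], replicates=2, sample_size=100,
               flip_noise=0.05, seed=5)
    eb = assay(b, times=[2.0, 5.0], replicates=2, sample_size=100,
               flip_noise=0.05, seed=5)
    pd.testing.assert_frame_equal(ea, eb)


def test_marker_state_trajectory_of_an_endoderm_cell():
    cell = {
        "true_fate": "endoderm", "commitment_day": 3.0,
        "mesendoderm_entry_day": 2.0, "death_day": np.nan,
        "gfp_onset_day": np.nan, "cell_id": 0, "condition": "wt",
    }
    assert marker_state(cell, 0.0) == MarkerProfile(1, 0, 0, 0, 0, 0, 0)
    assert marker_state(cell, 2.5) == MarkerProfile(0, 1, 0, 1, 0, 0, 0)
    assert marker_state(cell, 4.0) == MarkerProfile(0, 1, 1, 0, 0, 0, 0)


def test_neuroectoderm_progresses_from_ectoderm_pattern_to_sox3_only():
    cell = {
        "true_fate": "neuroectoderm", "commitment_day": 6.0,
        "mesendoderm_entry_day": np.nan, "death_day": np.nan,
        "gfp_onset_day": 7.0, "cell_id": 0, "condition": "wt",
    }
    assert marker_state(cell, 6.5) == MarkerProfile(0, 0, 0, 0, 0, 1, 1)
    assert marker_state(cell, 8.0) == MarkerProfile(0, 0, 0, 0, 0, 0, 1)


def test_noiseless_census_assay_matches_truth():
    cfg = PopulationConfig(n_cells=400, residual_nanog_fraction=0.0,
                           death_hazard=0.0, seed=21)
    pop = simulate_population(cfg)
    events = assay(pop, times=[10.0], replicates=1, sample_size=400,
                   flip_noise=0.0, seed=1)
    assert len(events) == 400
    assert sorted(events["cell_id"]) == sorted(pop["cell_id"])

    observed = classify_table(events).to_numpy()
    merged = events.merge(pop, on="cell_id")
    gfp_on = merged["gfp_onset_day"] <= 10.0
    expected = merged["true_fate"].where(
        (merged["true_fate"] != "neuroectoderm") | gfp_on, "ectoderm"
    )
    assert (observed == expected.to_numpy()).all()


def test_assay_errors_when_sample_exceeds_alive_cells(wt_population):
    with pytest.raises(ValueError, match="alive"):
        assay(wt_population, times=[10.0], replicates=1,
              sample_size=len(wt_population), flip_noise=0.0, seed=1)


def test_flip_noise_rate_matches_binomial_expectation():
    cfg = PopulationConfig(n_cells=3000, residual_nanog_fraction=1.0,
                           fate_fractions={"ectoderm": 1.0},
                           death_hazard=0.0, seed=8)
    pop = simulate_population(cfg)  # every cell stays Nanog+
    flip = 0.05
    events = assay(pop, times=[5.0], replicates=1, sample_size=3000,
                   flip_noise=flip, seed=2)
    frac_flipped = (events["nanog"] == 0).mean()
    se = np.sqrt(flip * (1 - flip) / 3000)
    assert abs(frac_flipped - flip) < 3 * se


def test_cumulative_differentiation_is_monotone_and_bounded(wt_population):
    commit = wt_population["commitment_day"].to_numpy()
    grid = np.linspace(0, 10, 41)
    cdf = [(commit <= t).mean() for t in grid]
    assert np.all(np.diff(cdf) >= 0)
    assert cdf[-1] <= 1.0 - 0.0  # residual cells never commit
    residual = wt_population["commitment_day"].isna().mean()
    assert cdf[-1] <= 1.0 - residual + 1e-12


def test_stat3b_reduces_and_delays_ectoderm(wt_population, stat3b_population):
    def ecto(pop):
        mask = pop["true_fate"].isin(["ectoderm", "neuroectoderm"])
        return pop.loc[mask, "commitment_day"]

    wt, sb = ecto(wt_population), ecto(stat3b_population)
    # factor 0.5: stat3b ectoderm count ~ half of wt (binomial tolerance)
    n = len(wt_population)
    p_wt = len(wt) / n
    se = np.sqrt(p_wt / 2 * (1 - p_wt / 2) / n)
    assert abs(len(sb) / n - p_wt / 2) < 4 * se
    # delayed commitment: empirical CDF of stat3b lies to the right
    assert sb.mean() > wt.mean() + 0.5


def test_new_fate_counts_peak_near_truth_mean():
    cfg = PopulationConfig(n_cells=5000, flip_noise=0.0, seed=17)
    pop = simulate_population(cfg)
    events = assay(pop, times=np.arange(0.0, 11.0), replicates=3,
                   sample_size=500, flip_noise=0.0, seed=4)
    counts = new_fate_counts(events, "endoderm")
    peak_time = counts.loc[counts["count"].idxmax(), "time"]
    assert 2.0 <= peak_time <= 4.0


def test_differentiation_counts_gate_out_dead_cells(wt_population):
    events = assay(wt_population, times=[8.0], replicates=2, sample_size=500,
                   flip_noise=0.0, seed=6)
    counts = differentiation_counts(events)
    assert (counts["n_assayed"] <= 500).all()
    assert (counts["n_differentiated"] <= counts["n_assayed"]).all()


def test_survival_records_are_consistent_with_truth(wt_population):
    rec = survival_records(wt_population, horizon=10.0)
    assert len(rec) == len(wt_population)
    assert set(rec["event"]) <= {
        "neuroectoderm_commit", "death", "other_fate", "censored"
    }
    assert (rec["time"] >= 0).all() and (rec["time"] <= 10.0).all()
    # neuroectoderm events occur at the GFP onset time
    merged = rec.merge(wt_population, left_on="subject_id", right_on="cell_id")
    neuro = merged[merged["event"] == "neuroectoderm_commit"]
    assert np.allclose(neuro["time"], neuro["gfp_onset_day"])
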
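# Methods

This note documents the models behind `stemdiff`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Marker panel and classification

Differentiation status is a function of Nanog alone: Nanog⁺ cells are
undifferentiated regardless of the Foxa2/Noggin/Ap-2α cocktail, Nanog⁻
cells have differentiated. Germ-layer fate is an exact match of the six
non-Nanog calls against nine recognised signatures: mesendoderm
{Foxa2⁺Noggin⁺}, {Foxa2⁺}, {Noggin⁺}; endoderm {Foxa2⁺Hex⁺}, {Hex⁺};
mesoderm {Noggin⁺Tbx6⁺}, {Tbx6⁺}; ectoderm {Ap-2α⁺Sox3⁺}; neuroectoderm
{Sox3⁺ only}. The rule tables define nothing outside these rows, so any
other Nanog⁻ profile is reported as `unclassified` rather than being
snapped to a nearest fate: under 2% flip noise the dominant error mode is
a single spurious or missing call, and inventing a nearest-fate metric
would silently convert noise into biased lineage counts. Enumerating all
2⁷ = 128 profiles partitions them 64 / 3 / 2 / 2 / 1 / 1 / 55
(undifferentiated / mesendoderm / endoderm / mesoderm / ectoderm /
neuroectoderm / unclassified); this partition is frozen in the tests as a
regression oracle.

When ectodermal commitment is being counted, cells classified
`neuroectoderm` are included with `ectoderm`: neuroectoderm is modelled as
a progression of already-committed ectoderm, and excluding it would make
the ectoderm pattern count *decrease* as cells switch to the Sox3-only
state, corrupting the cumulative count the rate estimate differentiates.

## Synthetic populations

The generator draws, per cell: a fate (endoderm / mesoderm / ectoderm) or
permanent residency in the Nanog⁺ state; a commitment day from a Normal
truncated to the culture horizon; a mesendoderm entry day (endoderm and
mesoderm cells express the mesendoderm signature for a fixed lead time
before commitment); for a sub-fraction of ectoderm cells, progression to
the Sox3-only pattern after a lag (the Sox3-promoter-GFP onset used by the
survival analysis); and a death time from a constant per-day hazard.
Superimposing per-lineage Gaussian commitment rates yields the sigmoid
cumulative-differentiation curve the logistic model assumes, with plateau
1 − residual fraction.

Default truth parameters (units: days unless noted):

| parameter | default | rationale |
| --- | --- | --- |
| commitment mean | endoderm 3, mesoderm 7, ectoderm 7 | the hypothesised peak days the design loop is meant to recover |
| commitment SD | 1.0 per lineage | unstated upstream; 1 d makes the lineage waves distinguishable on a daily grid without being trivially sharp |
| fate fractions | endo 0.30 / meso 0.35 / ecto 0.35 | no published per-layer fractions for EB cultures; a near-even split keeps every lineage estimable from 500-cell samples |
| residual Nanog⁺ fraction | 0.05 | Nanog⁺ cells persist at day 10 in EB cultures but no fraction is reported; 5% is a visible-but-minor remnant |
| mesendoderm lead | 1.0 | endoderm precursors appear ~1–3 d before day-5 mesoderm/ectoderm markers; 1 d is the smallest round lead consistent with that ordering |
| neuroectoderm sub-fraction / lag | 0.5 / 1.0 | unreported; half-and-half maximises information for the competing-risks contrast |
| marker flip noise | 0.02 /call | typical order of compensated FACS mis-gating |
| death hazard | 0.02 /day | ~18% cumulative death by day 10, enough for death to matter as a competing risk without dominating |
| STAT3β ectoderm factor / delay | 0.5 / +1.0 d | encodes the predicted direction (reduced and delayed ectodermal commitment); magnitudes are study conditions, not claims |

Under the STAT3β condition the ectoderm fraction is multiplied by the
factor, the freed mass is reassigned to the other fates proportionally to
their wild-type fractions, and the ectoderm commitment mean is shifted by
the delay.

Assays sample cells without replacement per (time, replicate), record
viability (dead cells appear PI-positive with markers frozen at death;
downstream counts gate them out), and invert each marker call
independently with the flip probability.

What the generator does **not** emulate: continuous fluorescence
intensities, spectral spillover or compensation, doublets, spatial EB
structure, proliferation (populations are fixed cohorts), and any coupling
between lineages beyond the shared fate draw. Tests passing on this
generator therefore demonstrate correctness of the estimators under the
stated statistical assumptions — not robustness to optical artefacts or
growth dynamics of real cytometry data.

## Curve fitting

The cumulative proportion differentiated is fit by least squares with a
3-parameter logistic (plateau L ∈ (0, 1], rate k > 0, inflection t₀);
a binomial-likelihood refinement is available when per-time totals are
supplied. Initialisation: t₀ at the steepest observed rise, L at the
maximum proportion, k = 4·(max slope)/L. The solver is trust-region least
squares with tolerance 1e-12 and a 10⁴ evaluation cap; non-convergence
raises rather than returning a silent best effort. The SD handed to the
design loop is π/(k√3), the standard deviation of the logistic
distribution whose CDF the fitted curve is.

Per-lineage commitment rates are estimated from differences of cumulative
lineage counts between consecutive assay times, clipped at zero and
labelled at interval midpoints (labelling at the right edge biases the
peak by half an interval). A scaled Gaussian is fit to these rate counts;
a single-spike input cannot identify the width, so the SD is floored at
half the sampling interval and flagged.

## The iterative design loop

The sampling window for an estimate (μ, σ) is the uniform grid from μ − σ
to μ + σ + 1 inclusive. The one-day upper extension is deliberate: it
reproduces the published worked schedule (mean day 5, SD 2 → days 3–8)
exactly, and it guards the selection against the systematic rightward
skew of cumulative counts. Windows are clipped to the culture horizon
with a warning.

Each iteration assays every window time with the scheduled replicates and
selects the peak lexicographically: maximal mean count, ties broken by
minimal replicate SD, remaining ties by the earlier day. Two iterations
are run by default — 24-hour spacing with 3 replicates, then 12-hour
spacing with 5 — and the loop stops there: commitment timing is too
variable for finer grids to add information. The argmax day recenters the
next window (that is the stated update rule), but the *final* reported
estimate is the mean and SD of the Gaussian rate fit over the last
window, which pools every (time, replicate) point; the raw argmax is
quantised to the 12-h grid and jitters by ±0.5 d at realistic sample
sizes, while the fitted peak recovers the day-3 and day-7 truths to
within ~0.2 d at 5,000 cells. The second window's SD is capped at the
first's so windows never widen. Every window, count and estimate is
recorded in an audit trail that replays bit-for-bit from the seed.

In the closed-loop simulator source, the per-interval commitment count is
the difference of *aggregate* lineage counts classified at the interval
edges (each classification with independent flip noise). Differencing
aggregates is unbiased under flip noise; pairing individual cells across
the two classifications is not (a mis-called committed cell re-counts as
"new", adding a background that ramps with cumulative commitment), and a
destructive assay could not pair cells anyway.

## Sequential monitoring

All beta-binomial evaluation is in log space (gammaln/betaln), so states
up to N ~ 10⁶ are exact to floating point; the predictive mass function
is evaluated directly, not renormalised. Stopping thresholds default to
0.95 (superiority) and 0.05 (futility) on the predicted probability of
reaching the goal; both are configurable, as the framework prescribes
only that thresholds be fixed a priori. Credible intervals are
equal-tailed beta quantiles. The prior defaults to the flat Beta(1, 1);
`prior_sensitivity` sweeps a user grid (a Jeffreys–flat–informative grid
is conventional), reports posterior means, intervals and goal
probabilities per prior, and flags the analysis as prior-dominated when
the spread of posterior means exceeds a tolerance (default 0.1, chosen as
a visible fraction of the probability scale; it is a reporting flag, not
a test).

## Survival analysis

Records carry one event per cell: neuroectodermal commitment (at GFP
onset), death, commitment to another fate, or administrative censoring at
the horizon (the upstream source defines no censoring rule for cells
still uncommitted at day 10, so the horizon is used). Kaplan–Meier curves
and the log-rank test come from lifelines; the Aalen–Johansen CIFs are
accumulated in-package from the all-cause product-limit estimator, which
makes the conservation identity S(t) + Σₖ CIFₖ(t) = 1 hold exactly at
every event time (and is cross-checked against lifelines'
AalenJohansenFitter in the tests). Ties follow the standard convention:
events precede censorings at equal times. Log-rank p-values are reported
for description only.

## pCa calculator

Odds of malignancy are the product of feature likelihood ratios; pCa =
odds/(1 + odds). The management boundaries are inclusive on both sides —
pCa ≤ 0.05 observation, pCa ≥ 0.60 resection, biopsy between — matching
the worked management cases (a pCa of exactly 0.05 is managed by
observation). Zero benign counts are an error unless the 0.5/0.5
continuity correction is enabled. Thresholds are config-overridable since
their provenance is 1980s cost-effectiveness analyses.

## Problem sizes

The validation suite and the acceptance script use 5,000-cell populations
with 500-cell samples for end-to-end recovery (matching the scale of a
typical EB dissociation and FACS run), 10⁵ Monte-Carlo draws for
predictive-distribution checks, and 200 replicate fits for the logistic
bias check; smaller populations (800–3,000 cells) are used where only
directional or structural behaviour is asserted.

## Known limitations

- The logistic model assumes a single differentiation wave; with lineages
  peaking days apart the cumulative curve is a sigmoid mixture and the
  single-logistic t₀ lands between the waves. The design loop therefore
  seeds from the per-lineage rate fit, not from the pooled logistic.
- A decreasing differentiated count late in culture (death/detachment) is
  outside the monotone logistic; it is represented through the death
  hazard and viability gating, not by the curve model.
- The fate classifier discards information in off-table profiles; under
  heavy noise (flip ≫ 5%) the unclassified bin grows and lineage counts
  lose efficiency.
- Monitoring covers a single arm with a conjugate beta prior only; no
  two-arm comparisons, non-conjugate priors or MCMC.
- The simulator's STAT3β effect sizes are conditions for validating the
  machinery, not biological estimates.
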
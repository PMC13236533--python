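# Methods

`elderburden` implements the analytic core of a burden-of-disease trend
study for adults aged 70 years and over: ingestion of GBD-results-shaped
panels, segmented log-linear trend analysis, period rate ratios, a Shapley
three-factor decomposition of change in deaths, age-specific log-linear
projection with hindcast validation, and PAF / rate summaries. This note
records the models, the defaults, and the judgement calls.

## Data model

A `BurdenPanel` holds long-format annual observations keyed by
(measure, location, sex, age band, year) with a rate per 100,000
person-years and/or a count, each with 95% uncertainty bounds. The accepted
age bands are the six 5-year bands 70–74 … 95+, plus a `70+` aggregate
label that ordinarily only arises from aggregation. Ingestion is strict by
default: an age band outside the 70+ scope is an error (a permissive flag
drops such rows with a warning). Rates are stored per 100,000 exactly as in
the source; every internal conversion goes through the single constant
`RATE_SCALE = 100000` to avoid scale drift.

Populations are never taken from an external source: within any
stratum-year carrying both a rate and a count, the implied person-years are
reconstructed as `count / rate × 100000`. Aggregation over sex and/or age
sums counts and reconstructed populations and recomputes the rate as total
count / total population × 100,000 (equivalently, a population-weighted
mean of stratum rates). Uncertainty bounds are summed on the count scale
and divided by the total population — a perfect-dependence, conservative
approximation, since draw-level correlation is not available in
results-tool extracts. When a panel carries reported Both-sex rows and sexes
are collapsed, the aggregate is recomputed from Male + Female and checked
against the reported rows at ±0.5% relative; disagreement warns rather than
errors.

PAFs are computed as attributable / total-cause × 100 on counts by default;
a rate-based variant is equivalent only when the two panels share exactly
the same strata, and is offered behind a flag for that case.

## Segmented log-linear trends

For one stratum's annual rate series, candidate continuous piecewise-linear
models with 1–6 segments are fitted to ln(rate), with breakpoints
constrained to integer years and a minimum knot-to-knot spacing of 5
calendar years. The fitter enumerates every admissible breakpoint set
exhaustively and solves each candidate by least squares in a hinge basis
(intercept, year, `(year − b)+` per breakpoint); with ≲32 annual
observations and ≤6 segments the search space is small enough that
exactness costs nothing. The segment count is selected by

    BIC(k) = n·ln(RSS/n) + p·ln(n),  p = (#slopes) + (#breakpoints) + 1 = 2k,

with ties broken toward fewer segments. The parameter count convention is
isolated in one function so alternatives are swappable. RSS is floored at
`n × 1e-20` inside the BIC: on noiseless data every candidate that
interpolates would otherwise drive the log term to −∞ and the comparison
would be decided by floating-point noise; with the floor all interpolating
candidates tie and parsimony picks the true segment count. The floor sits
many orders of magnitude below the RSS of any realistically noisy series
(σ = 0.01 on the log scale gives RSS ≈ 3e-3 at n = 32) and many orders
above least-squares rounding residue.

The annual percent change of a segment with log-slope β is
APC = (exp(β) − 1) × 100, with the 95% CI obtained by transforming
β ± 1.96·SE. Standard errors are Newey–West (Bartlett kernel, maxlag 1),
as implemented by statsmodels OLS with `cov_type="HAC"`; no small-sample
correction is applied. Segment point slopes are taken from the constrained
piecewise fit; their SEs come from unconstrained per-segment refits on each
segment's own years (adjacent segments share their knot year). The
published convention for segment inference in joinpoint-style analyses is
ambiguous on this point; the refit convention is used because the
constrained joint covariance mixes information across the knot. The
full-period AAPC always comes from a separate single log-linear fit over
the whole series — never from a weighted average of segment APCs, which
estimates a different quantity.

Rates of exactly zero are an error, not silently floored: neither the
synthetic generator nor a 70+ extract of this cause should produce them,
and silent flooring would bias log-scale slopes.

Observations are unweighted; nothing in the uncertainty ribbons enters the
trend likelihood.

## Period rate ratios

Calendar years are binned into consecutive 5-year periods from the first
observed year; the terminal bin may be shorter (e.g. 2020–2021) and is
labelled by its actual span. A period's rate is the arithmetic mean of its
annual point rates, and its PRR is that mean divided by the reference
(first) period's mean. The reported PRR bounds divide the period's mean
lower/upper estimates by the reference period's *point* mean — an
asymmetric, deliberately descriptive rule: these are envelopes inherited
from the input uncertainty ribbons, not confidence intervals from a model.
A `min_coverage` flag can drop bins observed for less than a chosen
fraction of the nominal width (coverage is measured against the nominal
5-year width, so a fully observed 1-year tail still counts as 20%).

## Shapley three-factor decomposition

The death count in a demographic state is factorised as

    D = N · Σ_a c_a · m_a

with N the total 70+ population of the stratum, c the vector of age-band
population shares and m the vector of age-specific death rates per
person-year. This multiplicative form is the package's definition of the
three factors "population growth", "population aging" and "age-specific
rate change"; it is the standard demographic factorisation, but it is a
modeling choice — the factors' names do not determine a unique functional
form. Contributions to ΔD between a base and a final state are Shapley
values: the implementation enumerates all 3! factor-switching orders and
averages marginal effects, which guarantees exact additivity, symmetry
(order invariance) and zero contribution for any factor identical in both
states. The closed-form subset-weighted expression exists only as an
independent oracle in the test suite.

For "Both sexes" the default structure vector has twelve sex × age cells,
so the aging term captures shifts in both age and sex composition; a flag
(`structure="age"`) switches to six age-only cells on pre-pooled Both-sex
rows. Per-sex and both-sex decompositions are always reported separately
and never summed implicitly — the two conventions only coincide when the
sex composition is static.

Two baseline anchorings are first-class: `descriptive` uses the observed
panel state at the base year; `model_fitted` replaces it with the
projection model's fitted state at the anchor year, keeping the projected
decomposition internally consistent with the forecast (the sensitivity
analysis swaps one for the other).

## Projection and validation

For each age × sex stratum, two independent OLS fits on the log scale —
rate and reconstructed population — over a training window (default
2000–2021, the recent-trend window; hindcasting reuses the same machinery
with an earlier window). Rates are extrapolated with classical t-based
out-of-sample 95% prediction intervals on the log scale, exponentiated;
populations are projected as point paths without intervals, so count
uncertainty reflects rate uncertainty only — a documented simplification.
Counts are rate × population / 100,000 per stratum-year; aggregates sum
counts and populations, and aggregated bounds are sums of stratum bounds
(perfect dependence; a root-sum-square independence variant sits behind
`bounds="independent"`).

Hindcasting trains on 2000–2014 and scores 2015–2021 with
MAPE = mean(|obs − pred| / obs) × 100, MAE, RMSE and the share of test
years inside the 95% prediction interval.

Robustness of the aggregated-rate forecast is probed against two
alternatives fitted to the log of the series (positivity and comparability
with the primary model; natural-scale fitting is available behind a flag):
an unobserved-components model with a local linear trend, and an ARIMA
model with order selected by AIC over p, q ∈ {0, 1, 2}, d ∈ {0, 1}
(deterministic trend "c" for d = 0, drift "t" for d ≥ 1; candidates that
fail to fit are skipped). ARIMA fits use a concentrated scale — with a
profiled innovation variance the drift MLE on near-deterministic series is
exact to machine precision, where the unconcentrated optimizer stalls a few
parts in 1e6 short. Divergence is summarised by MAPD = mean over the
horizon of |alt − primary| / primary × 100 (directional: the primary path
is always the denominator) and the percentage difference in the final
horizon year. Non-convergence is flagged in the output, never raised.

## Synthetic data generator

The generator produces GBD-shaped panels with known ground truth so every
downstream stage is testable without external data. Per stratum: the rate
follows a continuous piecewise log-linear path (the step leaving a
breakpoint year already uses the next segment's slope, so the kink sits
exactly at the breakpoint), multiplied by lognormal noise exp(ε),
ε ~ N(0, σ²); the population grows exponentially and noiselessly; counts
are rate × population / 100,000 and inherit the rate noise; bounds are
symmetric relative bands `val × (1 ∓ h)`. One root seed is combined with a
CRC-32 hash of each stratum key into a per-stratum child generator, so
adding a stratum never perturbs the others.

The default conditions (`default_global_spec`) emulate the global 70+
panel: 12 strata (2 sexes × 6 bands) over 1990–2021; 1990 death-rate
baselines rising from ≈5 per 100,000 at 70–74 to ≈46 at 95+ (Female ×1.08,
Male ×0.92); a two-segment trend (log-slope +0.002 to 2004, −0.014 after)
mirroring the flat-then-declining shape typical of attributable stroke
mortality; 1990 populations falling from 80 M (70–74) to 1.5 M (95+) with
annual log-growth rising from 0.022 to 0.036 with age, so the age structure
shifts upward; σ = 0.01 (results-tool point estimates are smooth);
half-width h = 0.8 (attributable-burden UIs are wide). Under these
conditions the projection reproduces the canonical "rates down, numbers up"
pattern by construction.

What the generator does **not** emulate: draw-based asymmetric uncertainty,
spatial correlation across locations, covariate-driven estimation, cohort
effects, or non-lognormal measurement error. Passing tests therefore
demonstrate correctness of the analytic machinery under the stated data
model, not robustness of the upstream burden estimates themselves.

## Problem sizes

Tests and the acceptance script run on panels of 12 strata × 32 years
(384 observations), 50–200 seeded replicates for stochastic checks, and
1000 random states for the decomposition property suite. These sizes were
chosen to make every exhaustive oracle (breakpoint enumeration, permutation
enumeration) exact and fast.

## Known limitations

- Segment SEs from per-segment refits ignore the continuity constraint;
  near a weakly identified breakpoint the refit slope can differ from the
  constrained slope it is paired with.
- Aggregated uncertainty (perfect-dependence summation) overstates interval
  width when stratum errors are close to independent.
- The projection assumes continuation of within-window log-linear trends;
  no cohort effects, no external population forecasts, no structural
  breaks over the horizon.
- MAPD is directional; comparing primary-vs-alt and alt-vs-primary gives
  different numbers by construction.
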
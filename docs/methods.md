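# Methods

This note records the modelling choices behind mobiflux: the flow models and
their assumptions, the evaluation protocol, what the synthetic generator does
and does not emulate, and the numerical decisions that were genuinely open.

## Setting and data model

The unit of analysis is an egocentric star network: a hub country exchanges
daily OD flow counts with each of *n* counterpart countries, in two
directions (incoming = toward the hub, outgoing = from it). Locations carry
a population and a centroid; distances are great-circle (haversine) on a
sphere of radius 6371.0 km between centroids — country-level geometry is all
the models use, and finer resolutions (e.g. antenna-level positions) are out
of scope. Dates are ISO calendar dates with no time component. A missing
(date, pair) record is a zero flow, not missing-at-random: the data emulate
device counting, where absence of devices is an observation. The star
constraint (every record touches the hub on exactly one side) is a
validation flag, on by default, so general OD matrices remain admissible —
the radiation machinery needs them.

## Gravity model

`T_ij = K · m_i m_j · f(r_ij)` with `f(r) = exp(−βr)` or `r^(−β)`. Fitting
minimises the sum of squared residuals on **raw flows** (not log flows), so
large pairs dominate — consistent with evaluating by CPC, which is also
count-weighted. Initialisation is scale-aware: `β₀ = 1/median(r)`
(exponential) or 1 (power), and `K₀` solves the total-flow balance at `β₀`;
this keeps the optimizer conditioned regardless of the magnitude of the mass
products (~10¹³ and up). β is bounded below at 0; a fit ending at the bound
is flagged. If all pair distances are (numerically) equal the objective is
flat in β: the fit warns (`FlatResidualWarning`) and reports β at its
starting value rather than pretending identification.

Two fitting scopes exist because descriptive protocols differ: `per-day`
(default) refits `(K, β)` on each day's cross-section in-sample, letting the
scale track the day's total; `global` fits one pair over the pooled window.
Both are exposed in the library and the CLI.

## Radiation model

Scores use the canonical closed form
`p_ij = m_i m_j / ((m_i + s_ij)(m_i + m_j + s_ij))` by default, with
`s_ij` = total population strictly inside the circle of radius `r_ij`
centred at the origin, excluding both endpoints. A second form with
`(m_j + s_ij)` as the first factor is provided as `as_printed`, since that
variant also circulates in the literature; the two coincide whenever
`m_i = m_j`, and both are checked against an exhaustive-scan oracle. Ties at
exactly `r_ij` are measure-zero in generated worlds but deterministic: the
`strict` rule (default) excludes them, `inclusive` counts them. The
stochastic opportunity-sampling formulation of the model is deliberately not
implemented; the closed form is what the predictions use.

Absolute flows require an origin total `O_i`. On a star network only
hub-side totals are observable, so the dated star predictor distributes each
day's observed total: outgoing flows are the hub's score distribution scaled
to the day's total outflow (ordinary origin-outflow normalization), and
incoming flows distribute the day's total arrivals across origins in
proportion to each origin's score toward the hub. Matching totals by
construction means CPC then measures purely how well the *allocation* across
countries is predicted.

## CGM — stringency-aware negative-binomial gravity

The mean surface is
`μ = exp(ε + α log P_i + β log P_j + γ x(r) + δ₁ SI_i + δ₂ SI_j)` with
`x(r) = log r` (power family) or `r` (exponential family). Writing the
distance term as a free coefficient times `log r` or `r` — rather than
`log f(r)` with a decay rate already inside `f` — makes γ identifiable and
reproduces both decay families exactly (for power, `γ = −β`; for
exponential, `γ = −β` per km). Mass exponents α, β are free rather than
pinned to 1. SI stays on its raw 0–100 scale, so δ's are per-index-point
log-effects.

Counts are NB2: `Var = μ + μ²/κ` with dispersion `κ > 0` (note the
convention: statsmodels' `alpha` is `1/κ`). Coefficients and dispersion are
estimated jointly by maximum likelihood via statsmodels' NB2 model, warm-
started from a Poisson fit, BFGS with a Newton polish; the polish is skipped
when the dispersion estimate sits at the Poisson boundary (`alpha → 0`),
where the NB Hessian's polygamma terms are numerically hostile. The
log-likelihood trace is recorded and is monotone up to line-search
tolerance. Zero flows are kept as observations — NB handles zeros; dropping
them would bias δ's upward.

Fitting is pooled across days (per direction), because the δ's are
identified by temporal variation in SI; within a single day each country's
SI is one number and the hub's SI is a constant. On a one-direction star the
hub-side `log P` column is constant and therefore collinear with the
intercept. By default this raises a named `SingularDesignError`; with
`absorb_constant=True` (used by the per-direction pipeline) structurally
constant covariates are folded into the intercept, reported as NaN and
listed — predictions are unaffected because the absorbed term is constant.
Experiments that need all six coefficients (parameter recovery) pool both
directions, where every covariate varies.

## Evaluation metrics and protocol

CPC is `2 Σ min(g, r) / (Σ g + Σ r)`: symmetric, scale-invariant, in [0, 1],
and equal to the fraction of correctly allocated unit trips when totals
match (verified against a brute-force multiset-matching oracle). IG is
`Σ (r_i/N) log(r_i/g_i)` with natural log and the `0·log 0 = 0` convention;
a zero generated flow against a positive observed one would be infinite, so
generated entries are floored at a configurable ε (default 10⁻¹⁰) and the
floor count is reported. Both metrics are additionally checked against
independent literal re-implementations to 10⁻¹².

The per-day pair universe is the set of pairs present in the observed panel
that day; predictions for pairs outside it are an error (not silently
dropped), predictions missing an observed day are an error, and missing
predictions inside the universe count as zero. Summaries report mean/max/min
CPC, mean CPC over P1 (default 2020-03-05..2020-03-15, the window before
widespread interventions) and P2 (the remainder), and mean IG. Relative
improvement `rel(ŷ, y) = (ŷ − y)/y` is computed per day and averaged
(average of ratios), matching the reporting convention for daily CPC series.

**Matched-scope contrast.** The headline comparison — does modelling
stringency help? — holds the fitting scope fixed: CGM and gravity are each
fitted once per direction over the whole window, so the only difference
between them is the SI covariates. Comparing pooled CGM against *per-day*
gravity would instead hand gravity two free parameters per day (180 vs 6
over a 90-day window) and measure day-level in-sample adaptation, not the
value of the stringency terms. On stringency-driven synthetic worlds the
matched-scope gap is large (mean CPC ≈ 0.82 vs ≈ 0.32 at the default study
size) because a single stringency-blind gravity surface cannot track the
restriction-driven decline at all. Per-day gravity remains the pipeline's
default descriptive baseline.

## Synchrony

Global synchronicity is the Pearson correlation of two daily series over
their full (identical) date overlap; local synchronicity applies sliding
windows of size W ∈ {5, 10, 15, 20, 25} by default, step 1 day (the finest
available; overlapping windows, not tiles), reporting mean and median per W.
Windows where either sub-series is constant have undefined correlation and
are excluded from the aggregates — mapping them to 0 would bias the mean —
with the exclusion count reported. Windows below 3 points are rejected as
unstable. A window equal to the series length reproduces the global value
exactly.

## Synthetic worlds

The generator emulates the structure of an operator's roaming panel without
any real data: a hub (UK-like defaults: 67 M population at 51.5°N) plus
`n_countries` counterparts scattered uniformly in a European-like lat/lon
box (35–65°N, −10–40°E; an area-uniform sphere option exists), populations
log-normal around a median of 8 M with log-sd 1, and per-country stringency
trajectories that are 0 until an intervention date drawn in the first 20
days, rise linearly over a 5–15-day ramp, and hold a plateau drawn from
50–90. Flows are drawn per (date, pair) from Poisson or NB2 noise around a
gravity or CGM mean surface; the noiseless surface is emitted alongside for
oracle checks and equals the corresponding model module's `predict` output
to 10⁻¹⁰.

Default study size is 30 counterparts × 90 days from 2020-03-05, with flow
magnitudes of order 10²–10⁵ — large enough to identify the δ's, small
enough for desk-scale runs. Intercepts/scales are not free dials: the CGM ε
(and the gravity K) is solved so the median pre-intervention flow hits a
target magnitude (default 2000), which pins the flow scale to something
realistic independently of the drawn masses. The exponential-family CGM
truth uses γ = −0.001 per km (about one e-fold per 1000 km); the power
family uses γ = −1.5.

What the generator does **not** emulate — and hence what passing tests do
not establish about real roaming data: multi-SIM and multi-operator double
counting, market-share and device-mix biases, day-of-week and holiday
seasonality, reporting gaps, spatially correlated shocks other than
stringency, and any feedback from flows to policy. Tests demonstrate that
the estimators recover the mechanisms they model when those mechanisms
generated the data, not that real mobility obeys them.

## Numerical choices and degenerate inputs

* Undefined metrics (both totals zero, zero baseline, zero-variance series)
  return NaN markers, never 0/0 or silent zeros.
* Deterrence `r^(−β)` raises at `r = 0`; distance matrices force exact
  symmetry and a zero diagonal.
* Simulated mean surfaces guard against `exp` overflow (argument > 700)
  before sampling, with a named error.
* All randomness flows through `numpy.random.default_rng` seeds; worlds,
  panels and reference series are bit-identical under a fixed (config,
  seed), and the pipeline's `summary.csv` is byte-identical across reruns.
* Recovery experiments derive separate world/noise seeds per replicate from
  a base seed and record per-parameter bias, relative error and 95% Wald
  interval coverage; fit failures are counted, not fatal.

## Known limitations

* The CGM assumes log-linear SI effects with no lags; real policy responses
  act with delay and saturate.
* Per-direction CGM fits cannot identify the hub-side mass exponent
  (absorbed into the intercept) — an intrinsic limit of egocentric data,
  not of the implementation.
* The radiation star adaptation fixes each day's totals to the observed
  ones, so it predicts allocation only.
* Least-squares gravity fitting has no distributional model, hence no
  standard errors; use the CGM with δ's fixed at 0 when inference on
  gravity parameters is needed.
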
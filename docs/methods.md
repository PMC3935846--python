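# Methods

## The model

`qsdm` models the *full conditional distribution* of species biomass
(g AFDW m⁻², ash-free dry weight) given two hydrodynamic covariates:
maximal tidal current velocity `vel` (m s⁻¹, the peak over a full tidal
cycle) and inundation time `em` (% of the tidal cycle a site is
submerged).  For every quantile level τ the conditional quantile is a
linear surface with a first-degree interaction:

    Q_Y(τ | x) = β₀(τ) + β₁(τ)·vel + β₂(τ)·em + β₃(τ)·vel·em

Each β(τ) minimizes the summed check (pinball) loss
ρ_τ(r) = r·(τ − 1{r<0}).  Fitting a dense grid of levels — the standard
grid runs from 0.01 to 0.99 in steps of 0.02, 50 levels — turns the
family of fits into a discrete estimate of the conditional inverse CDF at
every covariate combination.

The scientific rationale is minimum-law (Liebig) limitation: the measured
covariates bound what biomass *can* occur, while unmeasured subsidiary
factors (food, recruitment, disturbance, biotic interactions) suppress
individual samples below that bound, producing zero-inflated,
heteroscedastic scatter that central estimators describe poorly.  Upper
quantiles estimate the potential niche; the whole quantile spectrum
reproduces the realistic scatter with no distributional assumption.

Assumptions worth stating explicitly:

* every conditional quantile is linear in (vel, em, vel·em) — no spline
  transforms are offered;
* samples are independent given covariates: endogenous spatial
  autocorrelation (aggregation, propagation, facilitation) is not
  modelled and can bias the ratio of low to high quantiles for strongly
  patchy species;
* the influence of the unmeasured factors is stationary: extrapolating a
  fitted spectrum to a new scenario assumes the suppression structure
  carries over.

## Estimation

Each level is fitted independently by solving the exact linear program

    min_{β,u,v}  τ·1ᵀu + (1−τ)·1ᵀv   s.t.  Xβ + u − v = y,  u,v ≥ 0

with the HiGHS solver (`scipy.optimize.linprog`).  The LP optimum *is*
the check-loss minimum, so the fitted loss is reproducible to solver
precision; two candidate solutions within 1e−8 relative loss are treated
as equivalent optima.  `sample_quantile` (the no-covariate case) uses the
classical order-statistic solution and takes the *lower endpoint* when
the minimizing set is an interval (nτ integral) — a deterministic tie
rule.  Rank-deficient designs are rejected naming the term set; LP
failures are reported with the solver status and the τ level.

Independently fitted levels can cross.  Fits are deliberately left
unconstrained (matching per-τ estimation); *monotone rearrangement*
(sorting each prediction vector along τ) is applied at prediction time,
before any inverse-CDF use.  Rearrangement preserves the multiset of
values, is idempotent, and guarantees a valid discrete inverse CDF.
Negative fitted quantiles are retained in raw predictions; they are
mapped to zero only at the biomass-interpretation layer (suitability
maps, sampled biomass), where a zero encodes absence.

## Model selection

Candidate term sets are ranked by AIC averaged over the fitted τ grid.
For a quantile fit the AIC is computed under the asymmetric-Laplace
working likelihood: with σ̂ = (1/n) Σ ρ_τ(rᵢ), the maximized
log-likelihood is n·(log(τ(1−τ)) − log σ̂ − 1) and AIC = 2k − 2·logL
with k coefficients.  This is a convention (the same one quantreg's
`AIC.rq` uses), not a likelihood claim; it is documented here because no
canonical AIC exists for check-loss fits.  A perfect fit (σ̂ = 0) is
reported as −∞ with a warning.

## Bootstrap out-of-bag calibration

For each level: the observation table is resampled with replacement
(n draws); the model is fitted on the resample and predicts the
observations never drawn (out-of-bag, on average ≈ 36.8% of rows).
Pairs (predicted τ-quantile, observed biomass) are *pooled across
iterations* — pooling, rather than per-iteration averaging, builds the
large population the class quantiles need.  The pooled pairs are split
into 10 *equal-frequency* classes of the predicted value (stable order:
predicted value, then sample id; class sizes differ by at most one).
Equal-frequency classes are used instead of equal-width bins because they
guarantee every class enough points for a stable sample quantile;
`class_scheme="width"` is available for comparison.  Per class the τ
sample quantile of the observed biomasses is compared with the mean
predicted value, and an OLS line of observed on predicted summarizes the
agreement: slope ≈ 1, intercept ≈ 0, r ≈ 1 indicate calibration.
Default is 5000 iterations for production runs; the tests use 60–200
iterations, which leaves visibly wider class noise and is reflected in
their tolerances.  Levels whose observed class quantiles are all zero do
not predict occurrence; they are retained and flagged, and
`occurrence_threshold_tau` reports the largest occurring level.

## Scenario products

**Habitat suitability (potential biomass)** is the τ = 0.975 surface
clamped at zero.  A slightly sub-optimal quantile is used instead of the
maximum because the maximum is volatile under outliers.

**Realized biomass** samples each cell's conditional distribution: u ~
Uniform(0, 1), clamped to the fitted range [0.01, 0.99] (the inverse CDF
is held constant beyond the fitted levels — no tail extrapolation), then
piecewise-linear interpolation of the rearranged quantile vector at u,
then clamping at zero.  Continuous u with interpolation is the default
(`tau_sampling="discrete"` snaps to the nearest fitted level); it is
smoother and contains the discrete scheme as a limit.  Draws are
independent across cells; a spatially correlated sampling scheme is not
offered.

**Stocks**: T = Σ S·bᵢ over valid cells of surface S (m²), reported in
g AFDW and split *exactly* into intertidal (inundation < 100%) and
subtidal (= 100%) parts — the total is computed as the sum of the two
zone sums, so additivity is bit-exact.  Realized stocks average 5
independent sampling passes by default and keep per-simulation totals
for dispersion.  **Occurrence** is the percentage of cells whose biomass
reaches the lowest positive biomass observed in the training data
(configurable to use the suitability surface instead of a sampled map).
**Potential vs realized** reports realized/potential per zone (0.2 = 1:5,
0.1 = 1:10).  Unit helpers (g → kg/tonnes, AFDW → wet weight assuming a
96% loss from wet to dry) are explicit and never applied implicitly.

## Synthetic data generator

Because the original field observations and hydrodynamic scenario grids
are not redistributable, the package ships a generator whose statistical
structure matches what the analysis assumes, plus analytic oracles.

* **Rasters**: an elevation-like surface (a monotone cross-grid trend
  plus Gaussian-smoothed noise; kernel width scales with grid size)
  drives both layers.  The lowest 35% of cells form a contiguous
  subtidal region (inundation exactly 100%); intertidal cells grade
  towards drier values.  Velocity is higher over low-lying channel-like
  cells, giving the negative velocity–inundation correlation of a tidal
  basin.  Default cell area 625 m² (25 m grid).  Everything is
  deterministic given the seed.
* **Observations**: covariates drawn uniformly from raster cells (or the
  covariate box); biomass y = max(0, B(x)·U) where B(x) is the
  linear-with-interaction bound and U = 0 with probability p₀, else
  U ~ Uniform(0, 1).  The atom at zero yields the excess zeros of real
  abundance data while keeping every conditional quantile *exactly
  linear*: Q(τ|x) = 0 for τ ≤ p₀, else max(0, B(x)·(τ−p₀)/(1−p₀)).
* **Defaults**: β = (5, 20, 0.30, −0.25) — both covariates contribute
  comparable biomass spans over velocity ∈ [0, 1.5] m s⁻¹ and
  inundation ∈ [0, 100]%, B(x) stays strictly positive over the whole
  box, and the negative interaction gives a dome-like ridge (optimal
  inundation decreases as current stress rises); p₀ = 0.3 gives ≈ 30%
  zero samples, a plausible value for a common benthic species.
* **Oracles**: `true_conditional_quantile` (closed form above),
  `analytic_expected_stock` (Σ S·(1−p₀)·max(0, B(x))/2) and
  `analytic_occupied_fraction` give exact targets for recovery,
  stock-consistency and occurrence tests.  Because the true conditional
  quantiles are linear in the covariates, `true_quantile_fit_grid`
  expresses them as a fitted-grid object, letting the mapping layer be
  exercised free of estimation error.  Under p₀ = 0 the expected
  realized-to-potential stock ratio is E[U]/0.975 = 0.5/0.975 ≈ 0.513.

What the generator does **not** emulate: spatial autocorrelation of the
*biomass residuals* (draws are independent given covariates), species
aggregation/patchiness, sampling-gear effects, temporal trends in the
suppression process, and measurement error in the covariates.  Tests
passing on this generator therefore demonstrate correctness of the
estimation and accounting machinery under the model's own assumptions,
not robustness to the ways real benthic data violate them.

## Numerical choices and problem sizes

* τ strictly inside (0, 1); grids strictly increasing; tau lookup in a
  fitted grid uses a 1e−9 absolute tolerance.
* Empty residual vectors have check loss 0 by convention; empty
  out-of-bag sets (possible at tiny n) skip the iteration with a log
  message.
* The pipeline derives one child seed per stage from the root seed via
  `SeedSequence.spawn`, so toggling a stage never changes another
  stage's stream, and a rerun with the same config is bit-identical.
* Test and acceptance problem sizes are chosen so the whole suite runs
  on a laptop-class single core: n = 5000 observations for recovery and
  stock checks, 100×100 scenario grids (10⁴ cells, standing in for the
  ~10⁶-cell production grids), 200 bootstrap iterations for calibration
  checks (5000 remains the production default), 5 stock simulations.

## Known limitations

* **Coefficient-level sampling noise.** At n = 5000 the componentwise
  sampling error of β̂(τ) is substantial: the raw interaction design is
  strongly collinear (vel·em correlates highly with its factors) and the
  uniform suppression noise has full relative width, so individual
  coefficients carry typical relative errors of 10–30% even though the
  *fitted surfaces* (predictions, stocks, calibration) are accurate to a
  few percent.  Empirically the maximum componentwise relative error
  across four τ levels exceeded 5% for 12 of 12 generator seeds tried,
  with median ≈ 30%, and it shrinks only as 1/√n.  Surface-level
  quantities, not raw coefficients, are the reliable outputs at these
  sample sizes.
* **Model-selection power at small n.**  The grid-averaged
  asymmetric-Laplace AIC favours dropping a truly absent interaction
  term only mildly on average (per-τ fits on the same data are strongly
  correlated, so averaging over the grid barely reduces the seed-to-seed
  variance of the AIC difference); at n = 200 the reduced model wins in
  roughly 70% of replicates, not overwhelmingly.  Model choice at small
  sample sizes should be treated as indicative.
* Occurrence percentages from a *sampled* map inherit Monte-Carlo noise;
  use `occurrence_basis="potential"` for a deterministic variant.
* No standard errors or confidence bands for coefficient paths are
  provided; no spatial block bootstrap; no B-spline covariate
  transforms.
* GeoTIFF I/O is not implemented; rasters are exchanged as ESRI ASCII
  grids.
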
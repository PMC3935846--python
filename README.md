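# qsdm — quantile-distribution species distribution modelling

`qsdm` is a species distribution modelling (SDM) toolkit for abundance
data that are zero-inflated, heteroscedastic and bounded above by the
measured environment — the typical shape of benthic biomass samples.
Instead of fitting a single central response, it models the **full
conditional quantile distribution** of biomass against environmental
covariates, which makes two complementary products available from one
model family:

* **habitat suitability** (the potential niche): the upper-boundary
  quantile surface (τ = 0.975), the maximum biomass the measured
  variables allow under minimum-law (Liebig) limitation;
* **realized abundance**: per-cell random draws from the fitted
  conditional distribution, reproducing the realistic scatter that
  unmeasured subsidiary factors impose below the boundary, and hence
  defensible **standing-stock totals** for whole scenario grids.

It is aimed at coastal/benthic ecologists combining large monitoring
datasets (one row per sample: maximal tidal current velocity in m s⁻¹,
inundation time in % of the tidal cycle, biomass in g AFDW m⁻²) with
gridded environmental scenarios from hydrodynamic models.

## The statistical core

For each quantile level τ the conditional quantile of biomass Y is
linear with a first-degree interaction,

    Q_Y(τ | x) = β₀(τ) + β₁(τ)·vel + β₂(τ)·em + β₃(τ)·vel·em,

where β(τ) minimizes the check (pinball) loss Σᵢ ρ_τ(yᵢ − xᵢᵀβ),
ρ_τ(r) = r·(τ − 1{r<0}).  Each level of a dense grid (0.01 to 0.99 in
steps of 0.02, 50 levels) is fitted independently by solving the
equivalent linear program exactly (HiGHS).  Monotone rearrangement turns
the per-cell predictions into a valid discrete inverse CDF; sampling it
with u ~ Uniform(0, 1) (clamped to the fitted range, piecewise-linear
interpolation, biomass clamped at 0) yields realized-biomass maps.
Standing stocks are T = Σ S·bᵢ over grid cells of surface S, split into
intertidal (inundation < 100%) and subtidal (= 100%) parts.  Model
validation is by bootstrap out-of-bag calibration: observed vs predicted
class quantiles regressed against the 1:1 line.  Model structure is
chosen by AIC (asymmetric-Laplace working likelihood) averaged over the
τ grid.

The original field data and hydrodynamic scenarios behind this kind of
analysis are typically not redistributable, so the package includes a
synthetic generator with matching statistical structure (smooth
correlated environmental layers with an intertidal/subtidal split;
biomass y = max(0, B(x)·U) with a point mass of zeros) together with
closed-form oracles (`true_conditional_quantile`,
`analytic_expected_stock`, `true_quantile_fit_grid`) so every stage is
testable end to end.  See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from qsdm import (SyntheticTruth, generate_observations, generate_raster,
                  fit_quantile_grid, default_tau_grid, calibrate_quantile,
                  realized_stock, potential_vs_realized,
                  minimum_positive_biomass, g_to_tonnes)

truth = SyntheticTruth()                      # beta=(5, 20, 0.3, -0.25), p0=0.3
obs = generate_observations(2000, truth, seed=42)
print(f"samples: {len(obs)}, zero fraction: {(obs.biomass == 0).mean():.3f}")

taus = np.unique(np.append(default_tau_grid(), 0.975))
fit = fit_quantile_grid(obs, taus=taus)
j = fit.tau_index(0.975)
print("upper-boundary (tau=0.975) coefficients:",
      np.round(fit.coefficients[j], 3).tolist())

cal = calibrate_quantile(obs, tau=0.5, n_iter=200, n_classes=10, seed=7)
print(f"calibration at tau=0.5: slope={cal.slope:.3f}, r={cal.r:.3f}")

raster = generate_raster((60, 80), truth, seed=9)
report = realized_stock(fit, raster, n_sim=5, seed=11,
                        threshold=minimum_positive_biomass(obs))
print(f"realized stock: {g_to_tonnes(report.realized_total):.2f} t AFDW "
      f"(intertidal {g_to_tonnes(report.realized_intertidal):.2f}, "
      f"subtidal {g_to_tonnes(report.realized_subtidal):.2f})")
print(f"potential stock: {g_to_tonnes(report.potential_total):.2f} t AFDW")
print(f"occurrence: {report.occurrence_total:.1f}% of cells")
print(f"realized/potential ratio: {potential_vs_realized(report)['total']:.3f}")
```

which prints:

```
samples: 2000, zero fraction: 0.300
upper-boundary (tau=0.975) coefficients: [4.916, 17.507, 0.29, -0.223]
calibration at tau=0.5: slope=0.822, r=0.990
realized stock: 26.52 t AFDW (intertidal 14.63, subtidal 11.89)
potential stock: 73.57 t AFDW
occurrence: 70.6% of cells
realized/potential ratio: 0.360
```

Reading the numbers: the generator suppresses 30% of samples to zero and
the fitted 0.975 surface is close to the true bound (5, 20, 0.3, −0.25).
The calibration line is tightly linear (r = 0.99); its slope below 1
reflects class-quantile shrinkage at this modest sample size and
iteration count (2000 samples, 200 bootstrap iterations — production runs
use 5000 iterations).  The realized stock is about 36% of the potential
stock: under the generator's uniform suppression the expected ratio is
(1 − p₀)/2 ÷ 0.975 ≈ 0.36, i.e. roughly a 1:3 realized-to-potential
ratio, and 70.6% of cells carry biomass at or above the smallest positive
observed value.

## Command-line pipeline

The same stages are scriptable from a YAML config:

```bash
qsdm run -c config.yaml          # simulate → fit → validate → map → stocks
qsdm fit -c config.yaml          # any single stage, against saved artifacts
```

Stage artifacts are plain text (observations CSV, ESRI ASCII grids,
JSON fit/calibration/stock reports); a manifest records the seeds, grid
cardinality and input digests of each run, and reruns with the same
config are bit-identical.  An empty config file is valid and uses the
production defaults (50-level τ grid, τ_upper = 0.975, 5000 bootstrap
iterations, 10 classes, 5 stock simulations).

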
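"""Synthetic tidal-basin data with known conditional distributions.

The generator emulates the inputs of the biomass-stock analysis at desk
scale: two smooth, correlated environmental layers (maximal tidal current
velocity and inundation time) with an intertidal/subtidal structure, and
benthic biomass observations that are zero-inflated, heteroscedastic and
bounded above by a linear-with-interaction niche surface.

The biomass model is a minimum-law suppression scheme: the measured
covariates set an upper bound

    B(x) = β₀ + β₁·velocity + β₂·inundation + β₃·velocity·inundation

on attainable biomass, and unmeasured subsidiary factors suppress each
sample below it by a random factor,

    y = max(0, B(x)·U),   U = 0 with probability p₀, else U ~ Uniform(0, 1).

The atom at U = 0 produces the excess zeros typical of benthic abundance
data while keeping every conditional quantile exactly linear in the
covariates: Q(τ | x) = 0 for τ ≤ p₀ and max(0, B(x)·(τ−p₀)/(1−p₀)) above —
the same family the regression module fits, so parameter recovery and stock
totals have closed-form oracles (:func:`true_conditional_quantile`,
:func:`analytic_expected_stock`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import OBSERVATION_COLUMNS, EnvironmentalRaster

#: Default upper-bound coefficients (intercept, velocity, inundation,
#: velocity:inundation).  Over the default covariate box (velocity 0–1.5
#: m s⁻¹, inundation 0–100%) both covariates contribute comparable biomass
#: spans, B(x) stays strictly positive, and the negative interaction gives
#: the dome-like ridge of a niche optimum at intermediate conditions.
DEFAULT_BETA = (5.0, 20.0, 0.30, -0.25)

#: Default suppression probability: ~30% of samples are exact zeros.
DEFAULT_P0 = 0.3


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of the synthetic biomass model.

    beta : upper-bound coefficients (intercept, b_vel, b_inund,
        b_interaction), mapping covariates to g AFDW m⁻².
    p0 : probability of total suppression (zero biomass), in [0, 1];
        p0 = 1 degenerates to a species that is always absent.
    velocity_range / inundation_range : covariate supports (m s⁻¹, %).
    seed : default seed for generators that are not passed one.
    """

    beta: tuple[float, float, float, float] = DEFAULT_BETA
    p0: float = DEFAULT_P0
    velocity_range: tuple[float, float] = (0.0, 1.5)
    inundation_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = tuple(float(b) for b in self.beta)
        if len(self.beta) != 4:
            raise ValueError("beta must have 4 entries")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must lie in [0, 1], got {self.p0}")
        for name, (lo, hi) in (
            ("velocity_range", self.velocity_range),
            ("inundation_range", self.inundation_range),
        ):
            if not lo < hi:
                raise ValueError(f"{name} must have min < max, got ({lo}, {hi})")

    def bound(self, velocity, inundation) -> np.ndarray:
        """Upper-bound surface B(x) (may be negative for some parameters)."""
        v = np.asarray(velocity, dtype=float)
        i = np.asarray(inundation, dtype=float)
        b0, b1, b2, b3 = self.beta
        return b0 + b1 * v + b2 * i + b3 * v * i


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Low-pass filtered white noise, standardized; constant on a 1-cell grid."""
    noise = rng.standard_normal(shape)
    sigma = max(min(shape) / 10.0, 1.0)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # degenerate grid (e.g. 1x1): no variance to standardize
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _rescale(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map a field linearly onto [lo, hi]; a constant field maps to midpoint."""
    fmin, fmax = field.min(), field.max()
    if fmax == fmin:
        return np.full_like(field, 0.5 * (lo + hi))
    return lo + (hi - lo) * (field - fmin) / (fmax - fmin)


def generate_raster(
    shape: tuple[int, int],
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
    cell_area: float = 625.0,
    subtidal_fraction: float = 0.35,
) -> EnvironmentalRaster:
    """Generate smooth, correlated velocity and inundation layers.

    An elevation-like surface (a cross-grid trend plus smoothed noise)
    drives both layers: the lowest ``subtidal_fraction`` of cells forms a
    contiguous permanently-submerged region (inundation exactly 100%);
    the remaining intertidal cells grade from the subtidal edge towards
    the top of the covariate's range.  Velocity is higher over low-lying
    (channel-like) cells, giving the two layers the negative correlation
    of a tidal basin.  Deterministic given ``seed``.

    ``cell_area`` defaults to 625 m² (25 m grid).
    """
    truth = truth or SyntheticTruth()
    nrows, ncols = int(shape[0]), int(shape[1])
    if nrows <= 0:
        raise ValueError(f"nrows must be positive, got {nrows}")
    if ncols <= 0:
        raise ValueError(f"ncols must be positive, got {ncols}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    # elevation: dominant monotone trend keeps the subtidal region contiguous
    trend = np.linspace(0.0, 1.0, nrows)[:, None] * np.ones((1, ncols))
    elevation = trend + 0.25 * _smooth_field((nrows, ncols), rng)

    vel_noise = _smooth_field((nrows, ncols), rng)
    v_lo, v_hi = truth.velocity_range
    velocity = _rescale(-elevation + 0.8 * vel_noise, v_lo, v_hi)

    i_lo, i_hi = truth.inundation_range
    subtidal = elevation < np.quantile(elevation, subtidal_fraction)
    # intertidal cells: lower elevation -> longer submerged, strictly < 100
    inter_hi = min(i_hi, 100.0 - 1e-6)
    inundation = _rescale(-elevation, i_lo, inter_hi)
    inundation = np.where(subtidal, 100.0, inundation)

    return EnvironmentalRaster(
        velocity=velocity,
        inundation=inundation,
        cell_area=float(cell_area),
        mask=np.ones((nrows, ncols), dtype=bool),
    )


def generate_observations(
    n: int,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
    raster: EnvironmentalRaster | None = None,
) -> pd.DataFrame:
    """Draw ``n`` synthetic benthic samples.

    Covariates are drawn uniformly from the valid cells of ``raster`` when
    given, otherwise uniformly over the truth's covariate ranges.  Biomass
    follows the suppression model y = max(0, B(x)·U) with an atom of mass
    p₀ at U = 0.  Deterministic given ``seed``.
    """
    truth = truth or SyntheticTruth()
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    if raster is not None:
        rows, cols = np.nonzero(raster.mask)
        pick = rng.integers(0, rows.size, size=n)
        velocity = raster.velocity[rows[pick], cols[pick]]
        inundation = raster.inundation[rows[pick], cols[pick]]
    else:
        velocity = rng.uniform(*truth.velocity_range, size=n)
        inundation = rng.uniform(*truth.inundation_range, size=n)

    u = rng.uniform(0.0, 1.0, size=n)
    suppressed = rng.uniform(0.0, 1.0, size=n) < truth.p0
    u = np.where(suppressed, 0.0, u)
    biomass = np.maximum(0.0, truth.bound(velocity, inundation) * u)

    return pd.DataFrame(
        {
            "sample_id": np.arange(n),
            "velocity": velocity,
            "inundation": inundation,
            "biomass": biomass,
        },
        columns=OBSERVATION_COLUMNS,
    )


def true_conditional_quantile(x1, x2, tau: float, truth: SyntheticTruth) -> np.ndarray:
    """Exact conditional τ-quantile of biomass at covariates (x1, x2).

    Under the suppression model the quantile is 0 for τ ≤ p₀ and
    max(0, B(x)·(τ−p₀)/(1−p₀)) above.  Vectorized over x1/x2.
    """
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly inside (0, 1), got {tau}")
    B = truth.bound(x1, x2)
    if tau <= truth.p0:
        return np.zeros_like(B)
    scale = (tau - truth.p0) / (1.0 - truth.p0)
    return np.maximum(0.0, B * scale)


def true_quantile_fit_grid(truth: SyntheticTruth, taus) -> "QuantileFitGrid":
    """The truth's conditional quantiles expressed as a fitted-grid object.

    Because Q(τ|x) = B(x)·(τ−p₀)/(1−p₀) (for τ > p₀, zero below) is linear
    in the covariates, the true conditional distribution is exactly
    representable in the model family: coefficient row β·(τ−p₀)/(1−p₀),
    or zeros for τ ≤ p₀.  Useful as an oracle input to the mapping layer,
    isolating it from estimation error.
    """
    from .regression import QuantileFitGrid, _validate_grid

    taus = _validate_grid(taus)
    beta = np.asarray(truth.beta)
    if truth.p0 >= 1.0:
        scale = np.zeros(taus.size)
    else:
        scale = np.maximum(0.0, taus - truth.p0) / (1.0 - truth.p0)
    return QuantileFitGrid(
        taus=taus,
        terms=("velocity", "inundation", "interaction"),
        coefficients=scale[:, None] * beta[None, :],
        check_loss=np.zeros(taus.size),
        n_obs=1,  # synthetic oracle: no observations behind it
    )


def analytic_expected_stock(raster: EnvironmentalRaster, truth: SyntheticTruth) -> float:
    """Expected realized standing stock Σ S·E[y | x_cell] over valid cells.

    E[y | x] = (1−p₀)·B(x)/2 where B(x) ≥ 0; cells with B(x) < 0 contribute
    exactly 0 (the truncation removes all mass).  Units: g AFDW.
    """
    B = truth.bound(raster.velocity, raster.inundation)
    mean = (1.0 - truth.p0) * np.maximum(0.0, B) / 2.0
    return float(raster.cell_area * mean[raster.mask].sum())


def analytic_occupied_fraction(
    raster: EnvironmentalRaster, truth: SyntheticTruth, threshold: float
) -> float:
    """Fraction of valid cells with P(y ≥ threshold) under the truth model.

    For threshold t > 0 and B(x) > 0 the per-cell probability is
    (1−p₀)·max(0, 1 − t/B(x)); averaging over cells gives the expected
    occupied fraction of a single realized map.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    B = truth.bound(raster.velocity, raster.inundation)[raster.mask]
    if threshold == 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (1.0 - truth.p0) * np.maximum(0.0, 1.0 - threshold / B)
    p = np.where(B <= 0, 0.0, p)
    return float(p.mean())
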
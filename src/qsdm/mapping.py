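"""Scenario mapping: suitability maps, conditional sampling, stock totals.

A fitted quantile grid applied to an environmental raster yields, per grid
cell, a discrete inverse CDF of biomass.  Two products follow:

* **habitat suitability** (potential biomass): the upper-boundary quantile
  surface (default τ = 0.975 — a slightly sub-optimal quantile, more robust
  than the maximum), clamped at zero;
* **realized biomass**: per cell an independent draw from the conditional
  distribution — u ~ Uniform(0, 1) clamped to the fitted τ range, evaluated
  through piecewise-linear interpolation of the rearranged quantile vector,
  then clamped at zero.  Negative fitted quantiles thus encode absence mass.

Standing stocks are T = Σ S·bᵢ over valid cells of surface S, split exactly
into intertidal (inundation < 100%) and subtidal (= 100%) parts.  Realized
stocks are averaged over several sampling passes (default 5); occurrence is
the percentage of cells whose biomass reaches the lowest value observed in
nature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvironmentalRaster
from .regression import QuantileFitGrid, predict_quantiles, rearrange_quantiles

DEFAULT_TAU_UPPER = 0.975


@dataclass
class ConditionalQuantileField:
    """Per-cell predicted quantile vectors aligned to a τ grid.

    values is (nrows, ncols, n_taus) with NaN at masked cells; after
    monotone rearrangement each cell's vector is a valid discrete inverse
    CDF (non-decreasing in τ).  ``clamped_at_zero`` records whether
    sampled biomasses are clamped at zero downstream (they are, by
    default policy).
    """

    taus: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    rearranged: bool = False
    clamped_at_zero: bool = True

    @property
    def is_monotone(self) -> bool:
        v = self.values[self.mask]
        if v.size == 0:
            return True
        return bool((np.diff(v, axis=-1) >= 0).all())


def build_conditional_field(
    fit: QuantileFitGrid,
    raster: EnvironmentalRaster,
    rearrange: bool = True,
) -> ConditionalQuantileField:
    """Evaluate the fitted quantile grid on every valid raster cell.

    With ``rearrange=True`` (default) each cell's quantile vector is
    sorted non-decreasingly (monotone rearrangement), guaranteeing a
    valid inverse CDF for sampling.
    """
    vel = np.where(raster.mask, raster.velocity, 0.0)
    inund = np.where(raster.mask, raster.inundation, 0.0)
    values = predict_quantiles(fit, vel, inund)
    if rearrange:
        values = rearrange_quantiles(values)
    values = np.where(raster.mask[..., None], values, np.nan)
    return ConditionalQuantileField(
        taus=fit.taus.copy(), values=values, mask=raster.mask.copy(), rearranged=rearrange
    )


def habitat_suitability_map(
    fit: QuantileFitGrid,
    raster: EnvironmentalRaster,
    tau_upper: float = DEFAULT_TAU_UPPER,
) -> np.ndarray:
    """Potential-biomass map from the upper-boundary quantile surface.

    Per valid cell max(0, x'β̂(τ_upper)); masked cells are NaN.  τ_upper
    must be one of the fitted levels (the error names the available ones).
    """
    j = fit.tau_index(tau_upper)
    vel = np.where(raster.mask, raster.velocity, 0.0)
    inund = np.where(raster.mask, raster.inundation, 0.0)
    pred = predict_quantiles(fit, vel, inund)[..., j]
    out = np.maximum(0.0, pred)
    return np.where(raster.mask, out, np.nan)


def sample_conditional_biomass(
    field: ConditionalQuantileField,
    seed=None,
    tau_sampling: str = "continuous",
) -> np.ndarray:
    """One realized-biomass map drawn from the per-cell conditional CDFs.

    Per valid cell: u ~ Uniform(0, 1) clamped to [τ_min, τ_max] (the
    inverse CDF is held constant beyond the fitted range — no tail
    extrapolation), evaluated by piecewise-linear interpolation between
    fitted quantiles (``tau_sampling="continuous"``) or snapped to the
    nearest fitted level (``"discrete"``), then clamped at zero.
    Deterministic given ``seed``.
    """
    if not field.rearranged or not field.is_monotone:
        raise ValueError(
            "conditional quantile field has crossing quantiles; apply "
            "monotone rearrangement (build_conditional_field(..., rearrange=True)) "
            "before sampling"
        )
    if tau_sampling not in ("continuous", "discrete"):
        raise ValueError(f"tau_sampling must be 'continuous' or 'discrete', got {tau_sampling!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taus = field.taus
    rows, cols = np.nonzero(field.mask)
    u = rng.uniform(0.0, 1.0, size=rows.size)
    u = np.clip(u, taus[0], taus[-1])
    cell_q = field.values[rows, cols]  # (n_valid, n_taus)
    if tau_sampling == "discrete":
        idx = np.abs(u[:, None] - taus[None, :]).argmin(axis=1)
        drawn = cell_q[np.arange(rows.size), idx]
    else:
        lo = np.clip(np.searchsorted(taus, u, side="right") - 1, 0, taus.size - 2)
        w = (u - taus[lo]) / (taus[lo + 1] - taus[lo])
        left = cell_q[np.arange(rows.size), lo]
        right = cell_q[np.arange(rows.size), lo + 1]
        drawn = left * (1.0 - w) + right * w
    if field.clamped_at_zero:
        drawn = np.maximum(0.0, drawn)
    out = np.full(field.mask.shape, np.nan)
    out[rows, cols] = drawn
    return out


def total_stock(
    biomass: np.ndarray, raster: EnvironmentalRaster
) -> dict[str, float]:
    """Standing stock T = Σ S·bᵢ (g AFDW), split by tidal zone.

    The total is computed as intertidal + subtidal over the same cell
    partition, so additivity is exact.
    """
    biomass = np.asarray(biomass, dtype=float)
    if biomass.shape != raster.shape:
        raise ValueError(
            f"biomass shape {biomass.shape} does not match raster {raster.shape}"
        )
    S = raster.cell_area
    inter = float(S * np.nansum(np.where(raster.intertidal_mask, biomass, 0.0)))
    sub = float(S * np.nansum(np.where(raster.subtidal_mask, biomass, 0.0)))
    return {"total": inter + sub, "intertidal": inter, "subtidal": sub}


def occurrence_fraction(
    biomass: np.ndarray, raster: EnvironmentalRaster, threshold: float
) -> dict[str, float]:
    """Percent of valid cells with biomass at or above the threshold.

    The threshold is the lowest biomass value observed in nature (the
    minimum positive training observation) unless stated otherwise.
    Reported for all valid cells and per tidal zone (a zone with no cells
    reports NaN).
    """
    if threshold < 0:
        raise ValueError("occurrence threshold must be non-negative")
    biomass = np.asarray(biomass, dtype=float)
    occupied = biomass >= threshold

    def pct(zone_mask: np.ndarray) -> float:
        nz = int(zone_mask.sum())
        if nz == 0:
            return float("nan")
        return float(100.0 * occupied[zone_mask].sum() / nz)

    return {
        "total": pct(raster.mask),
        "intertidal": pct(raster.intertidal_mask),
        "subtidal": pct(raster.subtidal_mask),
    }


def minimum_positive_biomass(observations: pd.DataFrame) -> float:
    """Default occurrence threshold: lowest positive observed biomass."""
    pos = observations["biomass"][observations["biomass"] > 0]
    if pos.empty:
        raise ValueError(
            "no positive biomass observations: occurrence threshold undefined"
        )
    return float(pos.min())


@dataclass
class StockReport:
    """Realized and potential standing stocks for one scenario (g AFDW)."""

    scenario_id: str
    realized_total: float
    realized_intertidal: float
    realized_subtidal: float
    potential_total: float
    potential_intertidal: float
    potential_subtidal: float
    occurrence_total: float | None
    occurrence_intertidal: float | None
    occurrence_subtidal: float | None
    occurrence_threshold: float | None
    tau_upper: float
    n_simulations_averaged: int
    per_simulation_totals: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StockReport":
        return cls(**json.loads(Path(path).read_text()))


def realized_stock(
    fit: QuantileFitGrid,
    raster: EnvironmentalRaster,
    n_sim: int = 5,
    seed=None,
    tau_upper: float = DEFAULT_TAU_UPPER,
    threshold: float | None = None,
    occurrence_basis: str = "sampled",
    tau_sampling: str = "continuous",
    scenario_id: str = "scenario",
) -> StockReport:
    """Estimate realized and potential stocks for one scenario raster.

    The conditional quantile field is built once (rearranged); ``n_sim``
    independent sampling passes are run and their stock totals averaged
    (per-simulation totals are kept for dispersion).  The potential stock
    integrates the τ_upper suitability surface.  Occurrence uses the first
    sampled map (``occurrence_basis="sampled"``) or the suitability map
    (``"potential"``); it is omitted when no threshold is given.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    if occurrence_basis not in ("sampled", "potential"):
        raise ValueError(
            f"occurrence_basis must be 'sampled' or 'potential', got {occurrence_basis!r}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    field_ = build_conditional_field(fit, raster, rearrange=True)
    suitability = habitat_suitability_map(fit, raster, tau_upper)
    potential = total_stock(suitability, raster)

    sims = []
    first_map = None
    for _ in range(n_sim):
        bmap = sample_conditional_biomass(field_, seed=rng, tau_sampling=tau_sampling)
        if first_map is None:
            first_map = bmap
        sims.append(total_stock(bmap, raster))
    realized = {
        key: float(np.mean([s[key] for s in sims]))
        for key in ("intertidal", "subtidal")
    }
    # same cell partition as total_stock: keep additivity bit-exact
    realized["total"] = realized["intertidal"] + realized["subtidal"]

    occ = {"total": None, "intertidal": None, "subtidal": None}
    if threshold is not None:
        basis = first_map if occurrence_basis == "sampled" else suitability
        occ = occurrence_fraction(basis, raster, threshold)

    return StockReport(
        scenario_id=scenario_id,
        realized_total=realized["total"],
        realized_intertidal=realized["intertidal"],
        realized_subtidal=realized["subtidal"],
        potential_total=potential["total"],
        potential_intertidal=potential["intertidal"],
        potential_subtidal=potential["subtidal"],
        occurrence_total=occ["total"],
        occurrence_intertidal=occ["intertidal"],
        occurrence_subtidal=occ["subtidal"],
        occurrence_threshold=threshold,
        tau_upper=float(tau_upper),
        n_simulations_averaged=int(n_sim),
        per_simulation_totals=[s["total"] for s in sims],
    )


def potential_vs_realized(report: StockReport) -> dict[str, float]:
    """Realized/potential stock ratios (total and per tidal zone).

    A ratio of 0.2 corresponds to 1:5, 0.1 to 1:10.  Zones with zero
    potential stock report NaN with a warning.
    """
    out = {}
    for zone in ("total", "intertidal", "subtidal"):
        pot = getattr(report, f"potential_{zone}")
        real = getattr(report, f"realized_{zone}")
        if pot == 0:
            warnings.warn(
                f"potential {zone} stock is zero: ratio undefined", RuntimeWarning,
                stacklevel=2,
            )
            out[zone] = float("nan")
        else:
            out[zone] = real / pot
    return out


# --- unit helpers (never applied implicitly) --------------------------------

def g_to_tonnes(grams: float) -> float:
    """Convert grams to metric tonnes."""
    return grams / 1e6


def g_to_kg(grams: float) -> float:
    """Convert grams to kilograms."""
    return grams / 1e3


def afdw_to_wet_weight(afdw: float, dry_fraction: float = 0.04) -> float:
    """Convert ash-free dry weight to wet weight.

    Default assumes a 96% loss from wet to dry weight, i.e. AFDW is 4% of
    wet weight.
    """
    if not 0 < dry_fraction <= 1:
        raise ValueError("dry_fraction must lie in (0, 1]")
    return afdw / dry_fraction
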
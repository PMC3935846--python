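"""Bootstrap out-of-bag calibration of fitted quantile models.

Each iteration resamples the observation table with replacement, fits the
quantile model on the resample (the training set) and predicts the
observations never drawn (the out-of-bag validation set).  Pooled over many
iterations, the (predicted quantile, observed biomass) pairs are split into
equal-frequency classes of the predicted value; within each class the τ
sample quantile of the observed biomasses is compared with the mean
predicted value.  A well-calibrated model puts the class points on the 1:1
line, summarized by an ordinary least-squares regression of observed on
predicted (slope, intercept, Pearson r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import (
    GridQuantileRegressor,
    _validate_tau,
    sample_quantile,
)

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    """Per-τ calibration summary.

    class_table has one row per prediction class: ``class_index``,
    ``mean_predicted`` (mean predicted τ-quantile in the class),
    ``observed_quantile`` (τ sample quantile of the observed biomasses),
    ``n`` validation pairs, and ``all_zero`` flagging classes whose
    observed biomasses are all exactly zero (quantiles not predicting
    occurrence).  slope/intercept/r summarize the OLS fit of observed on
    predicted across classes; for a calibrated model slope ≈ 1,
    intercept ≈ 0, r ≈ 1.
    """

    tau: float
    class_table: pd.DataFrame
    slope: float
    intercept: float
    r: float
    n_pairs: int
    n_iterations_used: int
    predicts_occurrence: bool = field(default=True)

    def summary(self) -> dict:
        return {
            "tau": self.tau,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "n_pairs": self.n_pairs,
            "n_iterations_used": self.n_iterations_used,
            "predicts_occurrence": self.predicts_occurrence,
        }


def bootstrap_split(
    data: pd.DataFrame, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap resample: (training indices, out-of-bag indices).

    Training is n draws with replacement (positional indices, repeats
    kept); out-of-bag are the rows never drawn.  The out-of-bag set can be
    empty at tiny n — callers should skip such iterations.  Deterministic
    given ``seed`` (an int or a Generator).
    """
    n = len(data)
    if n < 2:
        raise ValueError(f"need at least 2 observations to bootstrap, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    train = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), train)
    return train, oob


def _class_partition(order: np.ndarray, n_classes: int) -> list[np.ndarray]:
    """Split ordered indices into n_classes contiguous equal-frequency chunks."""
    return [c for c in np.array_split(order, n_classes)]


def calibrate_grid(
    data: pd.DataFrame,
    terms=("velocity", "inundation", "interaction"),
    taus=(0.5,),
    n_iter: int = 200,
    n_classes: int = 10,
    seed=None,
    class_scheme: str = "frequency",
) -> list[CalibrationResult]:
    """Out-of-bag calibration for every level of a τ grid.

    All levels share the same bootstrap splits (one grid fit per
    iteration), so each level's result is independent of the order the
    levels are given in.  Pairs are pooled across iterations before
    classing.  Returns results sorted by τ.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if n_classes < 2:
        raise ValueError(
            f"n_classes must be at least 2 to regress across classes, got {n_classes}"
        )
    if class_scheme not in ("frequency", "width"):
        raise ValueError(f"class_scheme must be 'frequency' or 'width', got {class_scheme!r}")
    taus = np.sort(np.unique(np.asarray(taus, dtype=float)))
    for t in taus:
        _validate_tau(t)

    X = data[["velocity", "inundation"]].to_numpy(dtype=float)
    y = data["biomass"].to_numpy(dtype=float)
    ids = data["sample_id"].to_numpy()
    rng = np.random.default_rng(seed)

    preds: list[np.ndarray] = []  # (n_oob, n_taus) blocks
    obs: list[np.ndarray] = []
    obs_ids: list[np.ndarray] = []
    used = 0
    for it in range(n_iter):
        train, oob = bootstrap_split(data, rng)
        if oob.size == 0:
            logger.info("iteration %d: empty out-of-bag set, skipped", it)
            continue
        est = GridQuantileRegressor(taus=taus, terms=terms)
        est.fit(X[train], y[train])
        preds.append(est.predict_quantiles(X[oob]))
        obs.append(y[oob])
        obs_ids.append(ids[oob])
        used += 1
    if used == 0:
        raise RuntimeError("every bootstrap iteration had an empty out-of-bag set")

    pred_mat = np.vstack(preds)
    y_all = np.concatenate(obs)
    id_all = np.concatenate(obs_ids)

    results = []
    for j, tau in enumerate(taus):
        p = pred_mat[:, j]
        # stable order: predicted value, ties by sample id
        order = np.lexsort((id_all, p))
        if class_scheme == "frequency":
            classes = _class_partition(order, n_classes)
        else:
            edges = np.linspace(p.min(), p.max(), n_classes + 1)
            bins = np.clip(np.digitize(p[order], edges[1:-1]), 0, n_classes - 1)
            classes = [order[bins == c] for c in range(n_classes)]
            classes = [c for c in classes if c.size > 0]
        rows = []
        for ci, idx in enumerate(classes):
            yc = y_all[idx]
            rows.append(
                {
                    "class_index": ci,
                    "mean_predicted": float(p[idx].mean()),
                    "observed_quantile": sample_quantile(yc, float(tau)),
                    "n": int(idx.size),
                    "all_zero": bool((yc == 0).all()),
                }
            )
        table = pd.DataFrame(rows)
        if table["mean_predicted"].nunique() > 1:
            reg = stats.linregress(table["mean_predicted"], table["observed_quantile"])
            slope, intercept, r = float(reg.slope), float(reg.intercept), float(reg.rvalue)
        else:  # degenerate: all classes predict the same value
            slope, intercept, r = float("nan"), float("nan"), float("nan")
        results.append(
            CalibrationResult(
                tau=float(tau),
                class_table=table,
                slope=slope,
                intercept=intercept,
                r=r,
                n_pairs=int(p.size),
                n_iterations_used=used,
                predicts_occurrence=bool((table["observed_quantile"] > 0).any()),
            )
        )
    return results


def calibrate_quantile(
    data: pd.DataFrame,
    terms=("velocity", "inundation", "interaction"),
    tau: float = 0.5,
    n_iter: int = 200,
    n_classes: int = 10,
    seed=None,
    class_scheme: str = "frequency",
) -> CalibrationResult:
    """Out-of-bag calibration of a single quantile level."""
    return calibrate_grid(
        data,
        terms=terms,
        taus=[tau],
        n_iter=n_iter,
        n_classes=n_classes,
        seed=seed,
        class_scheme=class_scheme,
    )[0]


def occurrence_threshold_tau(results: list[CalibrationResult]) -> float | None:
    """Largest τ whose calibration still predicts occurrence, if any.

    Mirrors reporting validation only 'up to' the level at which the
    model forecasts non-zero biomass.
    """
    taus = [r.tau for r in results if r.predicts_occurrence]
    return max(taus) if taus else None
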
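"""Linear quantile regression over a grid of quantile levels.

The conditional τ-quantile of biomass Y given covariates x = (velocity,
inundation) is modelled as Q_Y(τ | x) = x'β(τ) with a linear predictor in
velocity, inundation and their first-degree interaction.  Each β(τ) is the
minimizer of the check (pinball) loss

    ρ_τ(r) = τ·r   if r ≥ 0,   (τ − 1)·r   if r < 0,

summed over residuals r_i = y_i − x_i'β.  Fitting all levels of a dense τ
grid (default 0.01 to 0.99 in steps of 0.02, 50 levels) yields a discrete
estimate of the full conditional distribution, which downstream modules use
as a per-cell inverse CDF.

Each τ level is fitted independently by solving the equivalent linear
program exactly (HiGHS); fitted quantile curves may therefore cross, and
:func:`rearrange_quantiles` restores monotonicity by sorting (monotone
rearrangement) before any inverse-CDF use.

The scikit-learn style estimator :class:`GridQuantileRegressor` is the
primary interface; the module-level functions are thin wrappers kept for
pipeline and scripting use.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, RegressorMixin

#: covariate-derived terms; the intercept is always included.
TERMS = ("velocity", "inundation", "interaction")

#: nested candidate formulas for model selection, simplest first.
CANDIDATE_FORMULAS: tuple[tuple[str, ...], ...] = (
    (),
    ("velocity",),
    ("inundation",),
    ("velocity", "inundation"),
    ("velocity", "inundation", "interaction"),
)

# relative loss tolerance: two solutions within this are equivalent optima
LOSS_RTOL = 1e-8


def default_tau_grid() -> np.ndarray:
    """The standard grid: 0.01 to 0.99 in steps of 0.02 (50 levels)."""
    return 0.01 + 0.02 * np.arange(50)


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly inside (0, 1), got {tau}")
    return tau


def _validate_grid(taus) -> np.ndarray:
    taus = np.asarray(taus, dtype=float)
    if taus.ndim != 1 or taus.size == 0:
        raise ValueError("tau grid must be a non-empty 1-D sequence")
    if (taus <= 0).any() or (taus >= 1).any():
        raise ValueError("all tau levels must lie strictly inside (0, 1)")
    if (np.diff(taus) <= 0).any():
        raise ValueError("tau grid must be strictly increasing")
    return taus


def check_loss(residuals, tau: float) -> float:
    """Sum of the check (pinball) loss ρ_τ over a residual vector.

    An empty vector returns 0 by convention.  The result is non-negative
    and zero iff every residual is zero.
    """
    tau = _validate_tau(tau)
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        return 0.0
    return float(np.sum(r * (tau - (r < 0))))


def sample_quantile(y, tau: float) -> float:
    """The τ-th sample quantile as the check-loss minimizer.

    When the minimizing set is an interval (nτ integral), the lower
    endpoint is returned — the classical order-statistic solution,
    deterministic by construction.
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot take a quantile of an empty vector")
    ys = np.sort(y)
    n = y.size
    k = n * tau
    k_round = round(k)
    if abs(k - k_round) < 1e-9 and k_round >= 1:
        idx = k_round  # minimizer is [y_(k), y_(k+1)]: take the lower endpoint
    else:
        idx = math.ceil(k)
    return float(ys[min(idx, n) - 1])


def design_matrix(x, terms=TERMS) -> np.ndarray:
    """Build the design matrix [1, velocity?, inundation?, vel·inund?].

    ``x`` is (n, 2) with columns velocity and inundation; ``terms`` selects
    which covariate-derived columns appear (the intercept always does).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if x.shape[1] != 2:
        raise ValueError(f"expected 2 covariate columns, got {x.shape[1]}")
    if not np.isfinite(x).all():
        raise ValueError("covariates must be finite")
    unknown = set(terms) - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}; allowed: {TERMS}")
    cols = [np.ones(x.shape[0])]
    if "velocity" in terms:
        cols.append(x[:, 0])
    if "inundation" in terms:
        cols.append(x[:, 1])
    if "interaction" in terms:
        cols.append(x[:, 0] * x[:, 1])
    return np.column_stack(cols)


def term_names(terms=TERMS) -> list[str]:
    """Column names of :func:`design_matrix`, intercept first."""
    return ["intercept"] + [t for t in TERMS if t in terms]


def _solve_quantile_lp(D: np.ndarray, y: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    """Exact check-loss minimization as a linear program.

    min τ·1'u + (1−τ)·1'v  s.t.  Dβ + u − v = y,  u, v ≥ 0, β free.
    At the optimum u − v are the residuals, so the objective equals the
    summed check loss.
    """
    n, p = D.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    eye = sparse.eye(n, format="csc")
    A = sparse.hstack([sparse.csc_matrix(D), eye, -eye], format="csc")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(
            f"quantile LP failed at tau={tau}: {res.message} "
            f"(status {res.status}, {res.nit} iterations)"
        )
    beta = res.x[:p]
    # recompute the loss from residuals: immune to LP objective round-off
    return beta, check_loss(y - D @ beta, tau)


def _check_design(D: np.ndarray, terms) -> None:
    n, p = D.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")
    if np.linalg.matrix_rank(D) < p:
        raise ValueError(
            "design matrix is rank deficient; collinear terms among "
            f"{term_names(terms)}"
        )


class GridQuantileRegressor(BaseEstimator, RegressorMixin):
    """Linear quantile regression fitted independently at each τ level.

    Parameters
    ----------
    taus : array-like of float, optional
        Strictly increasing quantile levels in (0, 1).  Default is the
        standard 50-level grid (0.01 … 0.99, step 0.02).
    terms : tuple of str
        Covariate terms in the linear predictor, a subset of
        ``("velocity", "inundation", "interaction")``; the intercept is
        always included.

    Attributes
    ----------
    taus_ : (n_taus,) fitted quantile levels.
    coef_ : (n_taus, n_terms) covariate coefficients β(τ) (no intercept).
    intercept_ : (n_taus,) intercepts β₀(τ).
    check_loss_ : (n_taus,) achieved check loss per level.
    n_obs_ : number of training observations.

    Notes
    -----
    ``predict`` returns the conditional median surface (τ closest to 0.5)
    so the estimator composes with scikit-learn tooling;
    ``predict_quantiles`` returns the full raw per-τ matrix, which may be
    non-monotone across τ (crossing) and negative — rearrangement and
    zero-clamping are separate, explicit downstream steps.
    """

    def __init__(self, taus=None, terms: tuple[str, ...] = TERMS):
        self.taus = taus
        self.terms = terms

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have inconsistent lengths")
        if not np.isfinite(y).all():
            raise ValueError("y must be finite")
        taus = default_tau_grid() if self.taus is None else _validate_grid(self.taus)
        D = design_matrix(X, self.terms)
        _check_design(D, self.terms)
        coefs = np.empty((taus.size, D.shape[1]))
        losses = np.empty(taus.size)
        for j, tau in enumerate(taus):
            try:
                coefs[j], losses[j] = _solve_quantile_lp(D, y, float(tau))
            except RuntimeError as err:
                raise RuntimeError(f"fit failed at tau={tau}: {err}") from err
        self.taus_ = taus
        self.intercept_ = coefs[:, 0].copy()
        self.coef_ = coefs[:, 1:].copy()
        self.check_loss_ = losses
        self.n_obs_ = y.size
        self.n_features_in_ = X.shape[1]
        return self

    def _coef_table(self) -> np.ndarray:
        """(n_taus, k) coefficients with the intercept as first column."""
        return np.column_stack([self.intercept_, self.coef_])

    def predict_quantiles(self, X) -> np.ndarray:
        """Raw per-τ linear predictions, shape (n_samples, n_taus)."""
        D = design_matrix(np.asarray(X, dtype=float), self.terms)
        return D @ self._coef_table().T

    def predict(self, X) -> np.ndarray:
        """Conditional median prediction (grid level closest to τ = 0.5)."""
        j = int(np.argmin(np.abs(self.taus_ - 0.5)))
        return self.predict_quantiles(X)[:, j]

    def to_fit_grid(self) -> "QuantileFitGrid":
        return QuantileFitGrid(
            taus=self.taus_.copy(),
            terms=tuple(self.terms),
            coefficients=self._coef_table(),
            check_loss=self.check_loss_.copy(),
            n_obs=self.n_obs_,
        )


@dataclass
class QuantileFitGrid:
    """Serializable per-τ coefficient table of a fitted quantile grid.

    ``coefficients`` is (n_taus, k) with columns ordered as
    :func:`term_names` (intercept first).
    """

    taus: np.ndarray
    terms: tuple[str, ...]
    coefficients: np.ndarray
    check_loss: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        self.taus = _validate_grid(self.taus)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.check_loss = np.asarray(self.check_loss, dtype=float)
        k = len(term_names(self.terms))
        if self.coefficients.shape != (self.taus.size, k):
            raise ValueError(
                f"coefficients shape {self.coefficients.shape} inconsistent "
                f"with {self.taus.size} tau levels and {k} terms"
            )
        if self.check_loss.shape != (self.taus.size,):
            raise ValueError("check_loss must have one entry per tau level")
        if (self.check_loss < 0).any():
            raise ValueError("check loss cannot be negative")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    @property
    def term_names(self) -> list[str]:
        return term_names(self.terms)

    def tau_index(self, tau: float) -> int:
        """Index of a level in the grid (to float tolerance), or raise."""
        idx = np.flatnonzero(np.isclose(self.taus, tau, atol=1e-9))
        if idx.size == 0:
            raise ValueError(
                f"tau={tau} is not in the fitted grid; available levels: "
                f"{np.round(self.taus, 6).tolist()}"
            )
        return int(idx[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "formula": list(self.terms),
            "tau_grid": self.taus.tolist(),
            "coefficients": self.coefficients.tolist(),
            "check_loss": self.check_loss.tolist(),
            "n_obs": int(self.n_obs),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuantileFitGrid":
        payload = json.loads(Path(path).read_text())
        return cls(
            taus=np.asarray(payload["tau_grid"], dtype=float),
            terms=tuple(payload["formula"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            check_loss=np.asarray(payload["check_loss"], dtype=float),
            n_obs=int(payload["n_obs"]),
        )


def _table_xy(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = data[["velocity", "inundation"]].to_numpy(dtype=float)
    y = data["biomass"].to_numpy(dtype=float)
    return X, y


def fit_single_quantile(
    data: pd.DataFrame, terms=TERMS, tau: float = 0.5
) -> tuple[np.ndarray, float]:
    """Fit one quantile level; returns (coefficients, achieved check loss).

    Coefficient order follows :func:`term_names` (intercept first).
    """
    tau = _validate_tau(tau)
    X, y = _table_xy(data)
    D = design_matrix(X, terms)
    _check_design(D, terms)
    return _solve_quantile_lp(D, y, tau)


def fit_quantile_grid(data: pd.DataFrame, terms=TERMS, taus=None) -> QuantileFitGrid:
    """Fit the whole τ grid; levels are fitted independently."""
    est = GridQuantileRegressor(taus=taus, terms=terms)
    X, y = _table_xy(data)
    return est.fit(X, y).to_fit_grid()


def predict_quantiles(fit: QuantileFitGrid, x1, x2) -> np.ndarray:
    """Raw per-τ predictions X'β(τ) at covariates (x1 velocity, x2 inundation).

    Scalar inputs give a (n_taus,) vector; array inputs of shape s give
    (*s, n_taus).  Values may be negative and may cross across τ.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    scalar = x1.ndim == 0 and x2.ndim == 0
    x1, x2 = np.broadcast_arrays(np.atleast_1d(x1), np.atleast_1d(x2))
    shape = x1.shape
    D = design_matrix(np.column_stack([x1.ravel(), x2.ravel()]), fit.terms)
    out = D @ fit.coefficients.T
    if scalar:
        return out[0]
    return out.reshape(*shape, fit.taus.size)


def rearrange_quantiles(q) -> np.ndarray:
    """Monotone rearrangement: sort predicted quantiles along the τ axis.

    Independently fitted quantile curves can cross; sorting the per-point
    vector restores a valid (non-decreasing) discrete inverse CDF while
    preserving the multiset of values.  Idempotent.  Works on the last
    axis of any-dimensional input.
    """
    return np.sort(np.asarray(q, dtype=float), axis=-1)


def coefficient_paths(fit: QuantileFitGrid) -> pd.DataFrame:
    """Long-format coefficient paths β̂(τ): one row per (τ, term)."""
    names = fit.term_names
    rows = [
        {"tau": float(tau), "term": name, "estimate": float(fit.coefficients[i, j])}
        for i, tau in enumerate(fit.taus)
        for j, name in enumerate(names)
    ]
    return pd.DataFrame(rows, columns=["tau", "term", "estimate"])


def aic_quantile_model(data: pd.DataFrame, terms=TERMS, tau: float = 0.5) -> float:
    """AIC of a single-τ fit under the asymmetric-Laplace working likelihood.

    With σ̂ = (1/n) Σ ρ_τ(r_i), the maximized log-likelihood is
    n·(log(τ(1−τ)) − log σ̂ − 1) and AIC = 2k − 2·logL with k coefficients.
    A perfect fit (σ̂ = 0) returns −inf with a warning.
    """
    tau = _validate_tau(tau)
    beta, loss = fit_single_quantile(data, terms, tau)
    n = len(data)
    k = beta.size
    sigma = loss / n
    if sigma == 0.0:
        warnings.warn(
            f"perfect fit at tau={tau}: sigma-hat is 0, AIC reported as -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    loglik = n * (math.log(tau * (1.0 - tau)) - math.log(sigma) - 1.0)
    return 2.0 * k - 2.0 * loglik


def select_model(
    data: pd.DataFrame,
    formulas=CANDIDATE_FORMULAS,
    taus=None,
) -> pd.DataFrame:
    """Rank candidate formulas by AIC averaged over the τ grid, lowest first.

    Returns a DataFrame with columns ``formula`` (tuple of terms) and
    ``mean_aic``; ties keep the candidate order (stable sort).
    """
    taus = default_tau_grid() if taus is None else _validate_grid(taus)
    rows = []
    for terms in formulas:
        aics = [aic_quantile_model(data, terms, float(tau)) for tau in taus]
        rows.append({"formula": tuple(terms), "mean_aic": float(np.mean(aics))})
    out = pd.DataFrame(rows)
    return out.sort_values("mean_aic", kind="stable", ignore_index=True)
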
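"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's solver paths: the
exhaustive basic-solution search enumerates every exact-fit hyperplane
through p observations, which by LP theory contains a check-loss minimizer,
so it bounds what any correct fitter must achieve.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from qsdm import SyntheticTruth, generate_observations


def pinball(residuals: np.ndarray, tau: float) -> float:
    """Reference check loss, written independently of qsdm.check_loss."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def exhaustive_quantile_fit(D: np.ndarray, y: np.ndarray, tau: float):
    """Minimum check loss over all exact-fit basic solutions.

    Evaluates the loss at every β that interpolates p observations
    (non-singular subsets); the LP optimum is attained at such a vertex.
    Returns (best_beta, best_loss).
    """
    n, p = D.shape
    best_loss, best_beta = np.inf, None
    for subset in itertools.combinations(range(n), p):
        Ds = D[list(subset)]
        if abs(np.linalg.det(Ds)) < 1e-12:
            continue
        beta = np.linalg.solve(Ds, y[list(subset)])
        loss = pinball(y - D @ beta, tau)
        if loss < best_loss:
            best_loss, best_beta = loss, beta
    return best_beta, best_loss


@pytest.fixture(scope="session")
def default_truth() -> SyntheticTruth:
    return SyntheticTruth()


@pytest.fixture(scope="session")
def no_suppression_truth() -> SyntheticTruth:
    """Truth with p0 = 0: every conditional quantile is τ·B(x)."""
    return SyntheticTruth(p0=0.0)


@pytest.fixture(scope="session")
def small_observations(default_truth) -> pd.DataFrame:
    return generate_observations(400, default_truth, seed=11)


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """Eight hand-written samples spanning both covariates."""
    return pd.DataFrame(
        {
            "sample_id": range(8),
            "velocity": [0.1, 0.4, 0.8, 1.2, 0.2, 0.6, 1.0, 1.4],
            "inundation": [10.0, 90.0, 30.0, 70.0, 50.0, 20.0, 80.0, 40.0],
            "biomass": [0.0, 12.5, 8.0, 3.2, 20.1, 0.0, 5.5, 16.0],
        }
    )
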
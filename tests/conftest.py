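"""Shared fixtures.

The Monte-Carlo benchmark experiments are expensive, so they run once per
session and are shared between the acceptance tests and the ordering
property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mepm.data import AreaData, ModelParams, child_seed, cov_factor
from mepm.simulate import (
    scenario_config,
    run_mse_experiment,
    run_param_experiment,
    run_prediction_experiment,
)

MASTER_SEED = 20260929


def random_dataset(
    rng: np.random.Generator,
    D: int = 20,
    q0: int = 1,
    q1: int = 2,
    nu: float = 200.0,
    sigma_scale: float = 0.1,
    theta: ModelParams = None,
):
    """A small random dataset drawn from the model itself."""
    X0 = np.hstack([np.ones((D, 1)), rng.uniform(0, 1, (D, q0 - 1))]) \
        if q0 >= 1 else np.empty((D, 0))
    X1 = rng.uniform(1.0, 1.4, (D, q1))
    A = rng.normal(0, sigma_scale, (D, q1, q1))
    Sigma = np.einsum("dij,dkj->dik", A, A)
    if theta is None:
        beta = np.concatenate([[-3.5], rng.uniform(-0.5, 0.5, q0 + q1 - 1)])
        theta = ModelParams(beta=beta, phi=0.3)
    b1 = theta.beta[q0:]
    F = cov_factor(Sigma)
    u = np.einsum("dij,dj->di", F, rng.standard_normal((D, q1)))
    v = rng.standard_normal(D)
    X = np.hstack([X0, X1])
    mu = nu * np.exp(X @ theta.beta + u @ b1 + theta.phi * v)
    y = rng.poisson(mu)
    data = AreaData(y=y, nu=np.full(D, nu), X0=X0, X1=X1, Sigma=Sigma)
    return data, theta, mu


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so outcomes
    # do not depend on test execution order
    return child_seed(MASTER_SEED)


@pytest.fixture(scope="session")
def scenario1_param():
    """Scenario-1 parameter experiment at the benchmark scale (I=500)."""
    return run_param_experiment(scenario_config(1, I=500, seed=1))


@pytest.fixture(scope="session")
def scenario4_param():
    return run_param_experiment(scenario_config(4, I=500, seed=1))


@pytest.fixture(scope="session")
def scenario1_prediction():
    """Scenario-1 prediction experiment (I=500, L=500)."""
    return run_prediction_experiment(scenario_config(1, I=500, seed=1), L=500)


@pytest.fixture(scope="session")
def scenario4_prediction():
    return run_prediction_experiment(scenario_config(4, I=500, seed=1), L=500)


@pytest.fixture(scope="session")
def scenario1_mse_scaled():
    """Scaled-down bootstrap-MSE experiment (I=100, B=100)."""
    return run_mse_experiment(scenario_config(1, I=100, seed=1), B=100, L=200)
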
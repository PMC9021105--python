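"""Closed-form marginal moments of the measurement-error Poisson mixed model.

Conditionally on the random effect ``v_d ~ N(0,1)`` and the measurement
error ``u_d ~ N(0, Sigma_d)`` the count is Poisson with rate

    mu_d = nu_d * exp(x_d beta + u_d' beta1 + phi v_d).

The exponent is normal with mean ``x_d beta`` and variance
``beta1' Sigma_d beta1 + phi^2``, so the marginal moments follow from the
lognormal moment-generating function:

    E[y_d]   = nu_d   * exp(x_d beta +     q_d/2 + phi^2/2)
    E[y_d^2] = E[y_d] + nu_d^2 * exp(2 x_d beta + 2 q_d + 2 phi^2)

with ``q_d = beta1' Sigma_d beta1`` (Poisson law of total variance plus the
lognormal second moment).
"""

from __future__ import annotations

import numpy as np

from .data import AreaData, AreaRecord, DataError, ModelParams


def _linear_predictor(theta: ModelParams, data: AreaData) -> np.ndarray:
    if theta.p != data.p:
        raise DataError(
            f"theta has {theta.p} coefficients but the data has p = {data.p}"
        )
    return data.X @ theta.beta


def _quad_form(theta: ModelParams, data: AreaData) -> np.ndarray:
    """q_d = beta1' Sigma_d beta1 for every domain."""
    _, b1 = theta.split(data.q0)
    return np.einsum("dij,i,j->d", data.Sigma, b1, b1)


def log_marginal_mean(theta: ModelParams, data: AreaData) -> np.ndarray:
    """log E_theta[y_d | x_d] for every domain (overflow-safe form)."""
    eta = _linear_predictor(theta, data)
    q = _quad_form(theta, data)
    return np.log(data.nu) + eta + 0.5 * q + 0.5 * theta.phi ** 2


def marginal_mean(theta: ModelParams, data: AreaData) -> np.ndarray:
    """E_theta[y_d | x_d], marginal over u_d and v_d."""
    return np.exp(log_marginal_mean(theta, data))


def marginal_second_moment(theta: ModelParams, data: AreaData) -> np.ndarray:
    """E_theta[y_d^2 | x_d], marginal over u_d and v_d."""
    eta = _linear_predictor(theta, data)
    q = _quad_form(theta, data)
    m1 = marginal_mean(theta, data)
    a2 = data.nu ** 2 * np.exp(2.0 * eta + 2.0 * q + 2.0 * theta.phi ** 2)
    return m1 + a2


def conditional_rate(theta: ModelParams, rec: AreaRecord, u, v: float) -> float:
    """Poisson rate mu_d = nu_d exp(x_d beta + u' beta1 + phi v) for one domain.

    ``u`` is a realization of the measurement error of the error-prone
    block (length q1) and ``v`` a realization of the standard-normal
    random effect.
    """
    x0 = np.atleast_1d(np.asarray(rec.x0, dtype=float))
    x1 = np.atleast_1d(np.asarray(rec.x1, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if u.shape != x1.shape:
        raise DataError("u must have the dimension of the error-prone block")
    if theta.p != x0.size + x1.size:
        raise DataError("theta dimension does not match the record")
    b0, b1 = theta.beta[: x0.size], theta.beta[x0.size:]
    s = float(x0 @ b0 + x1 @ b1 + u @ b1 + theta.phi * float(v))
    return float(rec.nu) * float(np.exp(s))
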
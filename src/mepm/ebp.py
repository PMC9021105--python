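"""Empirical best prediction of domain probabilities and counts.

The best predictor of the domain probability p_d is its conditional
expectation given the observed count, a ratio of two (q1+1)-dimensional
integrals over the random effect v and the measurement error u.  The
integrals have no closed form and are approximated by antithetic Monte
Carlo: L draws of (u, v) plus their negations, averaged on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AreaData, ModelParams, child_seed, cov_factor
from .mm import FitResult


class PredictionError(RuntimeError):
    pass


@dataclass
class PredictionSet:
    """Per-domain predictions p_hat and mu_hat = nu * p_hat."""

    domain_id: np.ndarray
    p_hat: np.ndarray
    mu_hat: np.ndarray
    mc_se: np.ndarray
    L: int
    method: str


def _log_integrands(theta: ModelParams, data: AreaData, A: np.ndarray):
    """log integrands of the EBP numerator/denominator on draws A = exponent.

    A has shape (D, n): realizations of x_d beta + u' beta1 + phi v.
    """
    y = data.y[:, None]
    nu = data.nu[:, None]
    lam = nu * np.exp(A)
    logN = (y + 1.0) * A - lam
    logD = y * A - lam
    return logN, logD


def _ratio_and_se(logN: np.ndarray, logD: np.ndarray, antithetic: bool):
    """p_hat = mean(exp logN)/mean(exp logD) with a Monte-Carlo SE.

    The SE treats antithetic pairs (columns l and L+l) as the independent
    sampling units, via the delta method for a ratio of means.
    """
    D_, n = logD.shape
    shift = np.max(logD, axis=1, keepdims=True)
    if not np.all(np.isfinite(shift)):
        bad = np.where(~np.isfinite(shift.ravel()))[0]
        raise PredictionError(
            f"EBP denominator underflows for domain index {bad.tolist()}"
        )
    a = np.exp(logN - shift)
    b = np.exp(logD - shift)
    if antithetic:
        L = n // 2
        a = 0.5 * (a[:, :L] + a[:, L:])
        b = 0.5 * (b[:, :L] + b[:, L:])
    abar = a.mean(axis=1)
    bbar = b.mean(axis=1)
    if np.any(bbar <= 0):
        bad = np.where(bbar <= 0)[0]
        raise PredictionError(
            f"EBP denominator is numerically zero for domain index {bad.tolist()}"
        )
    p_hat = abar / bbar
    m = a.shape[1]
    if m > 1:
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        cab = np.mean((a - abar[:, None]) * (b - bbar[:, None]), axis=1) * m / (m - 1)
        rel = va / abar ** 2 + vb / bbar ** 2 - 2.0 * cab / (abar * bbar)
        mc_se = np.abs(p_hat) * np.sqrt(np.clip(rel, 0.0, None) / m)
    else:
        mc_se = np.zeros(D_)
    return p_hat, mc_se


def ebp_from_draws(
    fit: FitResult, data: AreaData, u: np.ndarray, v: np.ndarray
) -> PredictionSet:
    """EBP evaluated on explicitly supplied draws (plus their negations).

    ``u`` has shape (D, L, q1) and ``v`` shape (D, L); the antithetic
    negations are appended internally, giving 2L evaluation points.
    """
    theta = fit.theta_hat
    _, b1 = theta.split(data.q0)
    eta = data.X @ theta.beta
    w = np.einsum("dlk,k->dl", u, b1) + theta.phi * v  # (D, L)
    A = eta[:, None] + np.concatenate([w, -w], axis=1)  # antithetic pairs
    logN, logD = _log_integrands(theta, data, A)
    p_hat, mc_se = _ratio_and_se(logN, logD, antithetic=True)
    return PredictionSet(
        domain_id=data.domain_id,
        p_hat=p_hat,
        mu_hat=data.nu * p_hat,
        mc_se=mc_se,
        L=v.shape[1],
        method="EBP-MEPM",
    )


def ebp(fit: FitResult, data: AreaData, L: int = 500, seed: int = 0) -> PredictionSet:
    """Empirical best predictor of (p_d, mu_d) under the fitted model.

    Draws v ~ N(0,1) and u ~ N(0, Sigma_d), L of each per domain, and
    averages the numerator and denominator integrands over the draws and
    their negations (antithetic variates) on the log scale.
    """
    fit.require_converged()
    if L < 1:
        raise ValueError("L must be at least 1")
    rng = child_seed(seed)
    D, q1 = data.D, data.q1
    v = rng.standard_normal((D, L))
    z = rng.standard_normal((D, L, q1))
    F = cov_factor(data.Sigma)
    u = np.einsum("dij,dlj->dli", F, z)
    return ebp_from_draws(fit, data, u, v)


def synthetic_predictor(fit: FitResult, data: AreaData) -> PredictionSet:
    """Regression-only predictor p_d = exp(x_d beta_hat); no randomness."""
    fit.require_converged()
    p_hat = np.exp(data.X @ fit.theta_hat.beta)
    return PredictionSet(
        domain_id=data.domain_id,
        p_hat=p_hat,
        mu_hat=data.nu * p_hat,
        mc_se=np.zeros(data.D),
        L=0,
        method="SYN-MEPM",
    )
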
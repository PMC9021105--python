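"""Baseline area-level Poisson mixed model (no measurement error).

Maximum likelihood via the Laplace approximation: the marginal likelihood
integrates a scalar random effect v_d ~ N(0,1) out of

    y_d | v_d ~ Poisson(exp(o_d + x_d beta + phi v_d)),

where o_d is a fixed log-exposure offset (log nu_d by default).  The inner
integrand is log-concave in v, so the per-domain mode is found by a 1-D
Newton iteration and the outer optimization runs on the Laplace objective
with its exact gradient (implicit differentiation through the mode).

The empirical best predictor of mu_d under this model is a ratio of
one-dimensional integrals, evaluated by Gauss-Hermite quadrature (default)
or antithetic Monte Carlo.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize
from scipy.special import logsumexp

from .data import AreaData, ModelParams, child_seed
from .ebp import PredictionSet, _ratio_and_se
from .mm import FitResult, poisson_moment_init


def _inner_modes(eta, phi, y, max_iter=100, tol=1e-11):
    """Per-domain mode of h(v) = y(eta+phi v) - exp(eta+phi v) - v^2/2."""
    v = np.zeros_like(eta)
    for _ in range(max_iter):
        m = np.exp(eta + phi * v)
        g = phi * (y - m) - v
        if np.max(np.abs(g)) < tol:
            break
        h2 = phi * phi * m + 1.0  # = -h''(v) > 0
        step = g / h2
        # h is strictly concave; damp steps that overshoot into overflow
        step = np.clip(step, -10.0, 10.0)
        v = v + step
    return v


def _laplace_nll_grad(params, X, y, off):
    """Negative Laplace log-likelihood and its gradient in (beta, phi)."""
    beta, phi = params[:-1], params[-1]
    eta = off + X @ beta
    v = _inner_modes(eta, phi, y)
    s = eta + phi * v
    m = np.exp(s)
    t = phi * phi * m + 1.0
    ll = float(np.sum(y * s - m - 0.5 * v * v - 0.5 * np.log(t)))
    r = y - m
    # implicit differentiation through the mode v_hat(theta)
    common = r - 0.5 * phi * phi * m / t + 0.5 * phi ** 4 * m * m / (t * t)
    gbeta = X.T @ common
    gphi = float(
        np.sum(
            v * r
            - phi * m * (2.0 + phi * v) / (2.0 * t)
            - phi ** 3 * m * (r - phi * m * v) / (2.0 * t * t)
        )
    )
    return -ll, -np.concatenate([gbeta, [gphi]])


def fit_pm(
    data: AreaData,
    tol: float = 1e-8,
    max_iter: int = 200,
    offset: Optional[np.ndarray] = None,
    use_nu_offset: bool = True,
    phi_init: float = 0.1,
    phi_fixed: Optional[float] = None,
) -> FitResult:
    """Fit the Poisson mixed model by Laplace-approximate maximum likelihood.

    Parameters
    ----------
    offset : optional (D,) log-exposure; defaults to log(nu) when
        ``use_nu_offset`` is true, otherwise zero.  With a zero offset and a
        constant-column design, the intercept absorbs the exposure, which is
        the convention of the classical comparator fits.
    phi_fixed : hold the random-effect scale at this value and maximize over
        beta only (phi_fixed=0 reduces the model to the Poisson GLM).
    """
    data.check_fit_ready()
    X, y = data.X, data.y
    if offset is None:
        off = np.log(data.nu) if use_nu_offset else np.zeros(data.D)
    else:
        off = np.asarray(offset, dtype=float)
    # start at the Poisson GLM solution with the same offset, small phi
    glm_data = AreaData(
        y=data.y, nu=np.exp(off),
        X0=data.X0, X1=data.X1, Sigma=data.Sigma, domain_id=data.domain_id,
    )
    beta0 = poisson_moment_init(glm_data)
    gscale = max(1.0, float(np.sum(y)))
    if phi_fixed is not None:
        def obj(b):
            f, g = _laplace_nll_grad(
                np.concatenate([b, [phi_fixed]]), X, y, off
            )
            return f, g[:-1]
        x0 = beta0
    else:
        obj = _laplace_nll_grad
        x0 = np.concatenate([beta0, [phi_init]])
    res = optimize.minimize(
        obj,
        x0,
        args=() if phi_fixed is not None else (X, y, off),
        jac=True,
        method="BFGS",
        options={"gtol": tol * gscale, "maxiter": max_iter},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or gnorm <= 1e-4 * gscale
    if phi_fixed is not None:
        theta = np.concatenate([res.x, [abs(phi_fixed)]])
    else:
        theta = res.x.copy()
        theta[-1] = abs(theta[-1])  # the likelihood is symmetric in phi
    return FitResult(
        theta_hat=ModelParams(beta=theta[:-1], phi=float(theta[-1])),
        converged=converged,
        n_iter=int(res.nit),
        residual_norm=gnorm,
        method="ML-PM",
        psi_hat=float(theta[-1] ** 2),
        log_offset=off,
    )


def ebp_pm(
    fit: FitResult,
    data: AreaData,
    n_nodes: int = 25,
    L: Optional[int] = None,
    seed: int = 0,
) -> PredictionSet:
    """EBP of (p_d, mu_d) under the Poisson mixed model.

    By default the one-dimensional integrals over v are evaluated with
    ``n_nodes``-point Gauss-Hermite quadrature (deterministic); passing
    ``L`` switches to antithetic Monte Carlo with 2L draws.
    """
    fit.require_converged()
    theta = fit.theta_hat
    off = fit.log_offset if fit.log_offset is not None else np.log(data.nu)
    eta = off + data.X @ theta.beta  # log conditional mean at v = 0
    y = data.y[:, None]

    if L is None:
        nodes, weights = hermegauss(n_nodes)  # weight exp(-v^2/2)
        logw = np.log(weights / np.sqrt(2.0 * np.pi))
        S = eta[:, None] + theta.phi * nodes[None, :]
        lam = np.exp(S)
        logN = logsumexp(logw[None, :] + (y + 1.0) * S - lam, axis=1)
        logD = logsumexp(logw[None, :] + y * S - lam, axis=1)
        mu_hat = np.exp(logN - logD)
        mc_se = np.zeros(data.D)
        Lout = 0
    else:
        rng = child_seed(seed)
        v = rng.standard_normal((data.D, L))
        w = theta.phi * v
        S = eta[:, None] + np.concatenate([w, -w], axis=1)
        lam = np.exp(S)
        logNmat = (y + 1.0) * S - lam
        logDmat = y * S - lam
        mu_hat, mc_se = _ratio_and_se(logNmat, logDmat, antithetic=True)
        mc_se = mc_se / data.nu  # report the SE on the probability scale
        Lout = L

    p_hat = mu_hat / data.nu
    return PredictionSet(
        domain_id=data.domain_id,
        p_hat=p_hat,
        mu_hat=mu_hat,
        mc_se=mc_se,
        L=Lout,
        method="EBP-PM",
    )
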
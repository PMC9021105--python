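"""Method-of-moments fitting of the measurement-error Poisson mixed model.

The parameters theta = (beta, phi) solve the p+1 moment equations

    f_k(theta)   = sum_d E_theta[y_d] x_dk - sum_d y_d x_dk,   k = 1..p,
    f_p+1(theta) = sum_d E_theta[y_d^2]  - sum_d y_d^2,

which are driven to zero with a damped Newton-Raphson iteration.  The
moments depend on phi only through phi^2, so the iteration runs internally
on psi = phi^2 (unconstrained); this keeps the Jacobian column of the
random-effect scale well conditioned near zero and makes the sign
indeterminacy of phi explicit.  The reported estimate is
phi_hat = sqrt(max(psi_hat, 0)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
import pandas as pd

from .data import AreaData, DataError, ModelParams, child_seed, cov_factor


class FitError(RuntimeError):
    """Raised when an estimation routine cannot produce a valid fit."""


@dataclass
class FitResult:
    """Outcome of a model fit."""

    theta_hat: ModelParams
    converged: bool
    n_iter: int
    residual_norm: float
    method: str
    theta_cov: Optional[np.ndarray] = None
    psi_hat: Optional[float] = None  # raw (possibly negative) phi^2 estimate
    log_offset: Optional[np.ndarray] = None  # log-exposure used by PM fits

    def require_converged(self):
        if not self.converged:
            raise FitError(
                f"{self.method} fit did not converge "
                f"(residual max-norm {self.residual_norm:.3e})"
            )


# ---------------------------------------------------------------------------
# moment system in (beta, psi) coordinates


def _moment_pieces(beta, psi, data: AreaData):
    """First moment m1, and the lognormal tail a2 of the second moment."""
    eta = data.X @ beta
    b1 = beta[data.q0:]
    q = np.einsum("dij,i,j->d", data.Sigma, b1, b1)
    m1 = data.nu * np.exp(eta + 0.5 * q + 0.5 * psi)
    a2 = data.nu ** 2 * np.exp(2.0 * eta + 2.0 * q + 2.0 * psi)
    return m1, a2


def _sample_moments(data: AreaData) -> np.ndarray:
    """M_hat = (sum_d y_d x_dk for k=1..p, sum_d y_d^2)."""
    return np.concatenate([data.X.T @ data.y, [float(np.sum(data.y ** 2))]])


def _model_moments(beta, psi, data: AreaData) -> np.ndarray:
    m1, a2 = _moment_pieces(beta, psi, data)
    return np.concatenate([data.X.T @ m1, [float(np.sum(m1 + a2))]])


def _equations_psi(beta, psi, data: AreaData) -> np.ndarray:
    return _model_moments(beta, psi, data) - _sample_moments(data)


def _jacobian_psi(beta, psi, data: AreaData) -> np.ndarray:
    """Analytic Jacobian of the moment system w.r.t. (beta, psi)."""
    m1, a2 = _moment_pieces(beta, psi, data)
    b1 = beta[data.q0:]
    Sb = np.einsum("dij,j->di", data.Sigma, b1)  # (D, q1)
    # d eta_eff / d beta, where eta_eff = X beta + q/2 (+ psi/2)
    G = data.X.copy()
    G[:, data.q0:] += Sb
    p = data.p
    H = np.empty((p + 1, p + 1))
    dm1_db = m1[:, None] * G                              # (D, p)
    G2 = 2.0 * data.X
    G2[:, data.q0:] += 4.0 * Sb
    dm2_db = dm1_db + a2[:, None] * G2
    H[:p, :p] = data.X.T @ dm1_db
    H[:p, p] = data.X.T @ (0.5 * m1)
    H[p, :p] = dm2_db.sum(axis=0)
    H[p, p] = float(np.sum(0.5 * m1 + 2.0 * a2))
    return H


# ---------------------------------------------------------------------------
# public moment system in theta = (beta, phi) coordinates


def moment_equations(theta: ModelParams, data: AreaData) -> np.ndarray:
    """The (p+1,) vector f(theta) of moment equations."""
    if theta.p != data.p:
        raise DataError("theta dimension does not match the data")
    return _equations_psi(theta.beta, theta.phi ** 2, data)


def mm_jacobian(theta: ModelParams, data: AreaData) -> np.ndarray:
    """Analytic Jacobian H(theta) = df/d(beta, phi).

    The phi column is the psi column scaled by the chain-rule factor
    d psi / d phi = 2 phi, hence vanishes at phi = 0.
    """
    if theta.p != data.p:
        raise DataError("theta dimension does not match the data")
    H = _jacobian_psi(theta.beta, theta.phi ** 2, data)
    H[:, -1] *= 2.0 * theta.phi
    return H


# ---------------------------------------------------------------------------
# fitting


def poisson_moment_init(data: AreaData, max_iter: int = 100, tol: float = 1e-10):
    """Solve the error-free, no-random-effect system (Poisson log-linear fit).

    This is damped Newton (IRLS) for the Poisson GLM of y on X with offset
    log nu, which is exactly the phi = 0, Sigma = 0 moment system.  Used as
    the Newton starting value of :func:`fit_mm`.
    """
    X, y, nu = data.X, data.y, data.nu
    beta = np.zeros(data.p)
    gscale = max(1.0, float(np.max(np.abs(X.T @ y))))
    g = X.T @ (y - nu * np.exp(X @ beta))
    gnorm = float(np.max(np.abs(g)))
    for _ in range(max_iter):
        if gnorm <= tol * gscale:
            break
        mu = nu * np.exp(X @ beta)
        H = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular design in Poisson initialization") from exc
        damp = 1.0
        for _ in range(31):
            beta_new = beta + damp * step
            g_new = X.T @ (y - nu * np.exp(X @ beta_new))
            if np.all(np.isfinite(g_new)) and np.max(np.abs(g_new)) < gnorm:
                break
            damp *= 0.5
        else:
            break
        beta, g = beta_new, g_new
        gnorm = float(np.max(np.abs(g)))
    return beta


def fit_mm(
    data: AreaData,
    init: Optional[ModelParams] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    phi_init: float = 0.1,
) -> FitResult:
    """Fit theta = (beta, phi) by the method of moments (Newton-Raphson).

    ``tol`` is relative: convergence requires the max-norm of f(theta)
    to drop below ``tol * max(1, ||M_hat||_inf)``, where M_hat are the
    sample moments.  Damped steps (up to 10 halvings) are used whenever a
    full Newton step does not decrease the residual.
    """
    data.check_fit_ready()
    if init is not None:
        beta = init.beta.copy()
        psi = float(init.phi) ** 2
    else:
        beta = poisson_moment_init(data)
        psi = float(phi_init) ** 2
    scale = max(1.0, float(np.max(np.abs(_sample_moments(data)))))
    thresh = tol * scale

    f = _equations_psi(beta, psi, data)
    fnorm = float(np.max(np.abs(f)))
    n_iter = 0
    converged = fnorm <= thresh
    for n_iter in range(1, max_iter + 1):
        if converged:
            break
        H = _jacobian_psi(beta, psi, data)
        try:
            step = np.linalg.solve(H, f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, f, rcond=None)
        improved = False
        damp = 1.0
        for _ in range(11):  # full step + 10 halvings
            beta_new = beta - damp * step[:-1]
            psi_new = psi - damp * step[-1]
            f_new = _equations_psi(beta_new, psi_new, data)
            if np.all(np.isfinite(f_new)) and np.max(np.abs(f_new)) < fnorm:
                improved = True
                break
            damp *= 0.5
        if not improved:
            break
        beta, psi, f = beta_new, psi_new, f_new
        fnorm = float(np.max(np.abs(f)))
        converged = fnorm <= thresh

    phi_hat = float(np.sqrt(max(psi, 0.0)))
    return FitResult(
        theta_hat=ModelParams(beta=beta, phi=phi_hat),
        converged=bool(converged),
        n_iter=n_iter,
        residual_norm=fnorm,
        method="MM-MEPM",
        psi_hat=float(psi),
    )


# ---------------------------------------------------------------------------
# model simulation (shared by the bootstrap routines)


def draw_counts(theta: ModelParams, data: AreaData, rng: np.random.Generator):
    """Simulate (y, mu) from the fitted model, conditionally on the covariates.

    Draws u_d ~ N(0, Sigma_d) and v_d ~ N(0,1), forms the conditional rate
    mu_d = nu_d exp(x_d beta + u_d' beta1 + phi v_d) and samples
    y_d ~ Poisson(mu_d).
    """
    D, q1 = data.D, data.q1
    _, b1 = theta.split(data.q0)
    v = rng.standard_normal(D)
    F = cov_factor(data.Sigma)
    z = rng.standard_normal((D, q1))
    u = np.einsum("dij,dj->di", F, z)
    s = data.X @ theta.beta + u @ b1 + theta.phi * v
    mu = data.nu * np.exp(s)
    y = rng.poisson(mu).astype(float)
    return y, mu


# ---------------------------------------------------------------------------
# parameter variance and significance tests


def param_variance(
    data: AreaData,
    fit: FitResult,
    B: int = 300,
    variant: str = "A",
    seed: int = 0,
    max_fail_frac: float = 0.10,
) -> np.ndarray:
    """Parametric-bootstrap covariance matrix of theta_hat = (beta_hat, phi_hat).

    Variant "A" (Taylor / sandwich): bootstrap only the sample-moment vector
    M_hat and return H^-1 var_B(M_hat) H^-T evaluated at theta_hat.
    Variant "B": refit every bootstrap sample and return the empirical
    covariance of the refitted parameter vectors.
    """
    fit.require_converged()
    if B < 50:
        raise ValueError("B must be at least 50")
    if variant not in ("A", "B"):
        raise ValueError("variant must be 'A' or 'B'")
    theta = fit.theta_hat
    p = data.p

    if variant == "A":
        M = np.empty((B, p + 1))
        for b in range(B):
            rng = child_seed(seed, b)
            yb, _ = draw_counts(theta, data, rng)
            M[b] = _sample_moments(data.with_counts(yb))
        varM = np.cov(M, rowvar=False, bias=True)
        # Taylor expansion in (beta, psi = phi^2): the psi-space Jacobian is
        # nonsingular even at phi_hat = 0, where the phi column of the
        # theta-space Jacobian vanishes
        H = _jacobian_psi(theta.beta, theta.phi ** 2, data)
        Hinv = np.linalg.inv(H)
        cov_psi = Hinv @ varM @ Hinv.T
        # delta method psi -> phi; near the boundary, replace phi_hat by the
        # scale at which the psi noise dominates (var(phi_hat) ~ sd(psi)/4)
        phi_eff = max(theta.phi, float(cov_psi[-1, -1]) ** 0.25)
        J = np.eye(p + 1)
        J[-1, -1] = 1.0 / (2.0 * phi_eff) if phi_eff > 0 else 0.0
        cov = J @ cov_psi @ J.T
    else:
        thetas = []
        failed = 0
        for b in range(B):
            rng = child_seed(seed, b)
            yb, _ = draw_counts(theta, data, rng)
            try:
                fb = fit_mm(data.with_counts(yb))
            except (FitError, DataError):
                failed += 1
                continue
            if not fb.converged:
                failed += 1
                continue
            thetas.append(fb.theta_hat.as_vector())
        if failed > max_fail_frac * B:
            raise FitError(
                f"{failed}/{B} bootstrap refits failed (> {max_fail_frac:.0%})"
            )
        T = np.asarray(thetas)
        cov = np.cov(T, rowvar=False, bias=True)

    cov = (cov + cov.T) / 2.0
    return cov


def significance_test(
    fit: FitResult,
    theta_cov: np.ndarray,
    D: int,
    alpha: float = 0.10,
    names=None,
) -> pd.DataFrame:
    """Per-parameter t-based significance table.

    Confidence intervals are theta_k +/- t_{D-p, 1-alpha/2} sd(theta_k); a
    parameter is flagged significant when zero falls outside its interval.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    theta = fit.theta_hat.as_vector()
    p = theta.size - 1
    dof = D - p
    if dof <= 0:
        raise ValueError("need D > p for the t reference distribution")
    sd = np.sqrt(np.clip(np.diag(theta_cov), 0.0, None))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(sd > 0, theta / sd, np.inf * np.sign(theta))
        tval = np.where(theta == 0.0, 0.0, tval)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    lo, hi = theta - tcrit * sd, theta + tcrit * sd
    if names is None:
        names = [f"beta_{k}" for k in range(p)] + ["phi"]
    return pd.DataFrame(
        {
            "estimate": theta,
            "std_dev": sd,
            "t_value": tval,
            "p_value": pval,
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0) | (hi < 0),
        },
        index=pd.Index(names, name="parameter"),
    )
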
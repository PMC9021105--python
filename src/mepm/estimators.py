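"""Scikit-learn style estimator front-ends.

:class:`MEPMRegressor` wraps the method-of-moments fit of the
measurement-error Poisson mixed model; :class:`PoissonMixedRegressor`
wraps the Laplace-ML fit of the error-free baseline.  Both follow the
fit/predict protocol, with the caveat inherent to mixed models that the
empirical best predictor is an in-sample quantity: it conditions on the
observed count of each training domain.  Out-of-sample prediction is
therefore synthetic (regression-only).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .bootstrap import MSEResult, bootstrap_mse
from .data import AreaData
from .ebp import PredictionSet, ebp, synthetic_predictor
from .mm import fit_mm, param_variance, significance_test
from .pm import ebp_pm, fit_pm


def _assemble(X, y, nu, sigma, n_error_free):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be two-dimensional")
    D, p = X.shape
    q0 = int(n_error_free)
    if not 0 <= q0 <= p:
        raise ValueError("n_error_free must lie in [0, n_features]")
    q1 = p - q0
    if nu is None:
        nu = np.ones(D)
    if sigma is None:
        sigma = np.zeros((D, q1, q1))
    return AreaData(
        y=np.asarray(y), nu=np.asarray(nu, dtype=float),
        X0=X[:, :q0].reshape(D, q0), X1=X[:, q0:].reshape(D, q1),
        Sigma=np.asarray(sigma, dtype=float),
    )


class MEPMRegressor(RegressorMixin, BaseEstimator):
    """Area-level measurement-error Poisson mixed model, fitted by moments.

    Parameters
    ----------
    n_error_free : number of leading columns of X measured without error
        (the remaining columns carry the per-domain error covariances
        passed to :meth:`fit` as ``sigma``).
    tol, max_iter, phi_init : Newton-Raphson controls.

    Attributes
    ----------
    coef_ : (p,) fitted regression coefficients.
    phi_ : fitted random-effect scale (nonnegative).
    converged_, n_iter_, residual_norm_ : fit diagnostics.
    """

    def __init__(self, n_error_free: int = 1, tol: float = 1e-8,
                 max_iter: int = 100, phi_init: float = 0.1):
        self.n_error_free = n_error_free
        self.tol = tol
        self.max_iter = max_iter
        self.phi_init = phi_init

    def fit(self, X, y, nu=None, sigma=None):
        data = _assemble(X, y, nu, sigma, self.n_error_free)
        result = fit_mm(data, tol=self.tol, max_iter=self.max_iter,
                        phi_init=self.phi_init)
        self.data_ = data
        self.result_ = result
        self.coef_ = result.theta_hat.beta
        self.phi_ = result.theta_hat.phi
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.residual_norm_ = result.residual_norm
        self.n_features_in_ = data.p
        return self

    def predict_set(self, kind: str = "ebp", L: int = 500,
                    random_state: int = 0) -> PredictionSet:
        """In-sample prediction set (p_hat, mu_hat) for the training domains."""
        if kind == "ebp":
            return ebp(self.result_, self.data_, L=L, seed=random_state)
        if kind == "synthetic":
            return synthetic_predictor(self.result_, self.data_)
        raise ValueError("kind must be 'ebp' or 'synthetic'")

    def predict(self, X=None, nu=None, kind: str = "ebp", L: int = 500,
                random_state: int = 0):
        """Predicted counts mu_hat.

        Without ``X``: in-sample prediction for the training domains (EBP
        by default).  With ``X``: synthetic prediction for new domains.
        """
        if X is None:
            return self.predict_set(kind=kind, L=L, random_state=random_state).mu_hat
        X = np.asarray(X, dtype=float)
        if nu is None:
            nu = np.ones(X.shape[0])
        return np.asarray(nu, dtype=float) * np.exp(X @ self.coef_)

    def parameter_covariance(self, B: int = 300, variant: str = "A",
                             random_state: int = 0) -> np.ndarray:
        cov = param_variance(self.data_, self.result_, B=B, variant=variant,
                             seed=random_state)
        self.result_.theta_cov = cov
        return cov

    def summary(self, alpha: float = 0.10, B: int = 300,
                random_state: int = 0):
        """Significance table (estimate, sd, p-value, CI) for (beta, phi)."""
        if self.result_.theta_cov is None:
            self.parameter_covariance(B=B, random_state=random_state)
        return significance_test(
            self.result_, self.result_.theta_cov, D=self.data_.D, alpha=alpha
        )

    def estimate_mse(self, B: int = 300, L: int = 500,
                     random_state: int = 0) -> MSEResult:
        """Parametric-bootstrap MSE of the in-sample EBP."""
        return bootstrap_mse(self.data_, self.result_, B=B, L=L,
                             seed=random_state)


class PoissonMixedRegressor(RegressorMixin, BaseEstimator):
    """Baseline area-level Poisson mixed model (Laplace maximum likelihood)."""

    def __init__(self, n_error_free: int = 1, tol: float = 1e-8,
                 max_iter: int = 200, use_nu_offset: bool = True,
                 phi_init: float = 0.1):
        self.n_error_free = n_error_free
        self.tol = tol
        self.max_iter = max_iter
        self.use_nu_offset = use_nu_offset
        self.phi_init = phi_init

    def fit(self, X, y, nu=None, sigma=None):
        data = _assemble(X, y, nu, sigma, self.n_error_free)
        result = fit_pm(data, tol=self.tol, max_iter=self.max_iter,
                        use_nu_offset=self.use_nu_offset,
                        phi_init=self.phi_init)
        self.data_ = data
        self.result_ = result
        self.coef_ = result.theta_hat.beta
        self.phi_ = result.theta_hat.phi
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.residual_norm_ = result.residual_norm
        self.n_features_in_ = data.p
        return self

    def predict_set(self, n_nodes: int = 25, L: Optional[int] = None,
                    random_state: int = 0) -> PredictionSet:
        return ebp_pm(self.result_, self.data_, n_nodes=n_nodes, L=L,
                      seed=random_state)

    def predict(self, X=None, nu=None, n_nodes: int = 25,
                random_state: int = 0):
        if X is None:
            return self.predict_set(n_nodes=n_nodes,
                                    random_state=random_state).mu_hat
        X = np.asarray(X, dtype=float)
        if nu is None:
            nu = np.ones(X.shape[0])
        off = np.log(np.asarray(nu, dtype=float)) if self.use_nu_offset else 0.0
        return np.exp(off + X @ self.coef_)
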
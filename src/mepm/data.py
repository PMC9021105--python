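"""Core data containers for area-level count data with noisy covariates.

The model operates on one row per domain: an event count ``y_d``, a known
size parameter ``nu_d`` (the domain sample size in survey applications), a
block of error-free covariates ``x0``, a block of error-prone covariate
point estimates ``x1``, and the known measurement-error covariance matrix
``Sigma_d`` of the error-prone block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Raised when an input dataset violates the model's requirements."""


def _as_2d(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise DataError(f"{name} must be a 1- or 2-dimensional array")
    return a


@dataclass(frozen=True)
class ModelParams:
    """Model parameters theta = (beta, phi).

    ``beta`` stacks the coefficients of the error-free block first and the
    error-prone block second; ``phi`` is the (nonnegative) random-effect
    scale.  The sign of ``phi`` is not identified, so the nonnegative
    representative is stored.
    """

    beta: np.ndarray
    phi: float

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.ndim != 1 or not np.all(np.isfinite(beta)):
            raise DataError("beta must be a finite vector")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "phi", float(self.phi))
        if not np.isfinite(self.phi):
            raise DataError("phi must be finite")

    @property
    def p(self) -> int:
        return self.beta.size

    def as_vector(self) -> np.ndarray:
        """theta as a flat (p+1,) vector (beta, phi)."""
        return np.concatenate([self.beta, [self.phi]])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        return cls(beta=theta[:-1], phi=float(theta[-1]))

    def split(self, q0: int):
        """Return (beta0, beta1), the error-free / error-prone blocks."""
        return self.beta[:q0], self.beta[q0:]


@dataclass(frozen=True)
class AreaData:
    """A dataset of D domains.

    Parameters
    ----------
    y : (D,) nonnegative integer counts.
    nu : (D,) positive size parameters.
    X0 : (D, q0) error-free covariate values.
    X1 : (D, q1) error-prone covariate point estimates.
    Sigma : (D, q1, q1) per-domain measurement-error covariances
        (symmetric positive semidefinite).
    domain_id : optional sequence of D labels.
    """

    y: np.ndarray
    nu: np.ndarray
    X0: np.ndarray
    X1: np.ndarray
    Sigma: np.ndarray
    domain_id: np.ndarray = field(default=None)

    def __post_init__(self):
        y = np.asarray(self.y)
        if y.ndim != 1:
            raise DataError("y must be one-dimensional")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise DataError("y must contain nonnegative integers")
        y = y.astype(float)
        D = y.size
        nu = np.asarray(self.nu, dtype=float)
        if nu.shape == ():
            nu = np.full(D, float(nu))
        if nu.shape != (D,) or np.any(nu <= 0):
            raise DataError("nu must be positive with one value per domain")
        X0 = _as_2d(self.X0, "X0")
        X1 = _as_2d(self.X1, "X1")
        if X0.shape[0] != D or X1.shape[0] != D:
            raise DataError("covariate blocks must have one row per domain")
        q1 = X1.shape[1]
        Sigma = np.asarray(self.Sigma, dtype=float)
        if Sigma.shape != (D, q1, q1):
            raise DataError(
                f"Sigma must have shape (D, q1, q1) = ({D}, {q1}, {q1}); "
                f"got {Sigma.shape}"
            )
        if not np.allclose(Sigma, np.swapaxes(Sigma, 1, 2), atol=1e-10):
            raise DataError("each Sigma_d must be symmetric")
        # PSD check via eigenvalues of the symmetrized matrices
        w = np.linalg.eigvalsh((Sigma + np.swapaxes(Sigma, 1, 2)) / 2.0)
        if np.any(w < -1e-8 * max(1.0, float(np.max(np.abs(Sigma), initial=1.0)))):
            raise DataError("each Sigma_d must be positive semidefinite")
        ids = self.domain_id
        if ids is None:
            ids = np.array([f"d{i + 1}" for i in range(D)])
        else:
            ids = np.asarray(ids)
            if ids.shape != (D,):
                raise DataError("domain_id must have one label per domain")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "X0", X0)
        object.__setattr__(self, "X1", X1)
        object.__setattr__(self, "Sigma", Sigma)
        object.__setattr__(self, "domain_id", ids)

    @property
    def D(self) -> int:
        return self.y.size

    @property
    def q0(self) -> int:
        return self.X0.shape[1]

    @property
    def q1(self) -> int:
        return self.X1.shape[1]

    @property
    def p(self) -> int:
        return self.q0 + self.q1

    @property
    def X(self) -> np.ndarray:
        """Full (D, p) design matrix, error-free block first."""
        return np.hstack([self.X0, self.X1])

    def check_fit_ready(self):
        """Validate the dataset for moment fitting (D >= p+2, counts informative)."""
        if self.D < self.p + 2:
            raise DataError(
                f"need at least p+2 = {self.p + 2} domains to fit, got {self.D}"
            )
        if np.all(self.y == 0):
            raise DataError("all counts are zero; the model cannot be fitted")

    def subset(self, idx) -> "AreaData":
        return AreaData(
            y=self.y[idx],
            nu=self.nu[idx],
            X0=self.X0[idx],
            X1=self.X1[idx],
            Sigma=self.Sigma[idx],
            domain_id=self.domain_id[idx],
        )

    def with_counts(self, y) -> "AreaData":
        """A copy of the dataset with the counts replaced (used by bootstraps)."""
        return AreaData(
            y=y, nu=self.nu, X0=self.X0, X1=self.X1,
            Sigma=self.Sigma, domain_id=self.domain_id,
        )

    def record(self, d: int) -> "AreaRecord":
        return AreaRecord(
            domain_id=str(self.domain_id[d]),
            y=int(self.y[d]),
            nu=float(self.nu[d]),
            x0=self.X0[d],
            x1=self.X1[d],
            sigma=self.Sigma[d],
        )


@dataclass(frozen=True)
class AreaRecord:
    """A single domain's row (convenience view over :class:`AreaData`)."""

    domain_id: str
    y: int
    nu: float
    x0: np.ndarray
    x1: np.ndarray
    sigma: np.ndarray

    def as_dataset(self) -> AreaData:
        return AreaData(
            y=np.array([self.y]),
            nu=np.array([self.nu]),
            X0=np.asarray(self.x0, dtype=float)[None, :],
            X1=np.asarray(self.x1, dtype=float)[None, :],
            Sigma=np.asarray(self.sigma, dtype=float)[None, :, :],
            domain_id=np.array([self.domain_id]),
        )


def cov_factor(Sigma: np.ndarray) -> np.ndarray:
    """Per-domain factor F_d with F_d F_d' = Sigma_d, robust to PSD matrices.

    Cholesky when possible, eigenvalue square root for singular matrices
    (e.g. Sigma_d = 0, for which the factor is exactly zero).
    """
    Sigma = np.asarray(Sigma, dtype=float)
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((Sigma + np.swapaxes(Sigma, 1, 2)) / 2.0)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)[:, None, :]


def child_seed(seed: int, *key: int) -> np.random.Generator:
    """A generator deterministically derived from (seed, key...).

    Every stochastic routine in the package draws from generators produced
    here, so that replicate b of a bootstrap (say) is reproducible in
    isolation.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))
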
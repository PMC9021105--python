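"""Method-of-moments system, Newton-Raphson fit, and variance estimation."""

import numpy as np
import pytest
import statsmodels.api as sm

from mepm.data import AreaData, DataError, ModelParams, child_seed
from mepm.mm import (
    FitError,
    draw_counts,
    fit_mm,
    mm_jacobian,
    moment_equations,
    param_variance,
    poisson_moment_init,
    significance_test,
)
from mepm.moments import marginal_mean, marginal_second_moment

from conftest import random_dataset


class TestMomentEquations:
    def test_zero_at_matched_first_moments(self, rng):
        """When the counts equal their model expectations, the first p
        equations vanish (the second-moment equation involves y^2 and is
        checked by the summation oracle below)."""
        data, theta, _ = random_dataset(rng, D=12)
        y_matched = marginal_mean(theta, data)
        # bypass integer validation: equations are linear in the y column
        f_obs = moment_equations(theta, data)
        # f_k = sum E[y]x_k - sum y x_k, so replacing y by E[y] means
        # f_k(matched) = f_obs_k + sum (y - E[y]) x_k = 0
        correction = data.X.T @ (data.y - y_matched)
        np.testing.assert_allclose(f_obs[:-1] + correction, 0.0, atol=1e-8)

    def test_poisson_degenerate_single_covariate(self):
        """Sigma=0, phi=0, single constant covariate: component 1 reduces to
        sum(nu) e^beta - sum(y)."""
        rng = child_seed(5)
        D = 8
        y = rng.poisson(5.0, D)
        data = AreaData(
            y=y, nu=np.full(D, 100.0), X0=np.ones((D, 1)),
            X1=np.empty((D, 0)), Sigma=np.zeros((D, 0, 0)),
        )
        beta = 0.3
        f = moment_equations(ModelParams(beta=[beta], phi=0.0), data)
        expected = np.sum(data.nu) * np.exp(beta) - np.sum(y)
        assert f[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_literal_resummation(self, rng):
        """D=5 instance equals an explicit per-record re-summation."""
        data, theta, _ = random_dataset(rng, D=5, q1=2)
        f = moment_equations(theta, data)
        m1 = marginal_mean(theta, data)
        m2 = marginal_second_moment(theta, data)
        expected = np.zeros(data.p + 1)
        for k in range(data.p):
            for d in range(5):
                x_dk = data.X[d, k]
                expected[k] += m1[d] * x_dk - data.y[d] * x_dk
        for d in range(5):
            expected[-1] += m2[d] - data.y[d] ** 2
        np.testing.assert_allclose(f, expected, rtol=1e-10)


class TestJacobian:
    @pytest.mark.parametrize("case", range(6))
    def test_matches_finite_differences(self, case):
        """Analytic Jacobian vs central differences, relative error < 1e-4."""
        rng = child_seed(2000 + case)
        data, theta, _ = random_dataset(
            rng, D=10, q1=int(rng.integers(1, 4))
        )
        H = mm_jacobian(theta, data)
        th = theta.as_vector()
        eps = 1e-6
        Hfd = np.empty_like(H)
        for j in range(th.size):
            hi, lo = th.copy(), th.copy()
            hi[j] += eps
            lo[j] -= eps
            Hfd[:, j] = (
                moment_equations(ModelParams.from_vector(hi), data)
                - moment_equations(ModelParams.from_vector(lo), data)
            ) / (2 * eps)
        scale = np.max(np.abs(Hfd))
        np.testing.assert_allclose(H, Hfd, atol=1e-4 * scale)

    def test_phi_column_vanishes_at_zero(self, rng):
        data, theta, _ = random_dataset(rng, D=6)
        H = mm_jacobian(ModelParams(beta=theta.beta, phi=0.0), data)
        np.testing.assert_allclose(H[:, -1], 0.0)


class TestFit:
    def test_parameter_recovery_large_d(self):
        """Consistency: D=1000 generated at theta*, recovered within 0.1."""
        rng = child_seed(77)
        data, theta, _ = random_dataset(rng, D=1000, q1=2, nu=300.0)
        fit = fit_mm(data)
        assert fit.converged
        err = fit.theta_hat.as_vector() - theta.as_vector()
        assert np.max(np.abs(err)) < 0.1

    def test_degenerate_system_matches_statsmodels_glm(self, rng):
        """The phi=0, Sigma=0 moment system is the Poisson GLM score; its
        solution matches an independent IRLS fit to 1e-6."""
        data, theta, _ = random_dataset(rng, D=40, sigma_scale=0.0)
        beta = poisson_moment_init(data)
        glm = sm.GLM(
            data.y, data.X, family=sm.families.Poisson(),
            offset=np.log(data.nu),
        ).fit()
        np.testing.assert_allclose(beta, glm.params, atol=1e-6)

    def test_converged_residual_below_tolerance(self, rng):
        data, _, _ = random_dataset(rng, D=60)
        fit = fit_mm(data, tol=1e-8)
        assert fit.converged
        f = moment_equations(fit.theta_hat, data)
        scale = max(1.0, float(np.max(np.abs(data.X.T @ data.y))))
        assert np.max(np.abs(f)) <= 1e-8 * scale * 1.01 + 1e-12

    def test_reordering_invariance(self, rng):
        data, _, _ = random_dataset(rng, D=30)
        perm = child_seed(3).permutation(30)
        fit1 = fit_mm(data)
        fit2 = fit_mm(data.subset(perm))
        np.testing.assert_allclose(
            fit1.theta_hat.as_vector(), fit2.theta_hat.as_vector(), atol=1e-7
        )

    def test_phi_reported_nonnegative(self, rng):
        """Even when the sample is underdispersed (psi_hat < 0), the
        reported phi is the nonnegative representative."""
        for k in range(5):
            data, _, _ = random_dataset(
                child_seed(4000 + k), D=25, sigma_scale=0.0,
                theta=ModelParams(beta=[-3.0, 0.1, -0.1], phi=0.0),
            )
            fit = fit_mm(data)
            assert fit.theta_hat.phi >= 0.0

    def test_all_zero_counts_rejected(self):
        data = AreaData(
            y=np.zeros(10, dtype=int), nu=np.full(10, 5.0),
            X0=np.ones((10, 1)), X1=np.linspace(0, 1, 10)[:, None],
            Sigma=np.full((10, 1, 1), 0.01),
        )
        with pytest.raises(DataError):
            fit_mm(data)


class TestParamVariance:
    def test_variants_agree(self, rng):
        """Taylor (A) and refit (B) bootstrap variances estimate the same
        asymptotic quantity."""
        data, theta, _ = random_dataset(rng, D=100, nu=300.0)
        fit = fit_mm(data)
        covA = param_variance(data, fit, B=1000, variant="A", seed=11)
        covB = param_variance(data, fit, B=1000, variant="B", seed=12)
        dA, dB = np.diag(covA)[:-1], np.diag(covB)[:-1]
        assert np.all(np.abs(dA - dB) <= 0.25 * np.maximum(dA, dB))

    def test_glm_limit(self, rng):
        """With no random effect and no measurement error the bootstrap
        variance of beta approaches the inverse Fisher information."""
        theta0 = ModelParams(beta=[-3.0, 0.2, -0.2], phi=0.0)
        data, _, _ = random_dataset(
            child_seed(55), D=200, sigma_scale=0.0, nu=500.0, theta=theta0
        )
        fit = fit_mm(data)
        cov = param_variance(data, fit, B=600, variant="B", seed=5)
        mu = marginal_mean(fit.theta_hat, data)
        fisher = data.X.T @ (data.X * mu[:, None])
        target = np.diag(np.linalg.inv(fisher))
        got = np.diag(cov)[:-1]
        assert np.all(np.abs(got - target) <= 0.25 * target)

    def test_variance_shrinks_with_d(self):
        """Doubling D roughly halves the trace of the covariance."""
        traces = []
        for D in (80, 160):
            data, _, _ = random_dataset(
                child_seed(60), D=D, nu=300.0,
                theta=ModelParams(beta=[-3.5, 0.3, -0.3], phi=0.3),
            )
            fit = fit_mm(data)
            cov = param_variance(data, fit, B=400, variant="A", seed=6)
            traces.append(np.trace(cov))
        ratio = traces[1] / traces[0]
        assert 0.25 < ratio < 0.85

    def test_unconverged_fit_rejected(self, rng):
        data, theta, _ = random_dataset(rng, D=30)
        from mepm.mm import FitResult

        bad = FitResult(theta_hat=theta, converged=False, n_iter=0,
                        residual_norm=1.0, method="MM-MEPM")
        with pytest.raises(FitError):
            param_variance(data, bad, B=100, seed=0)


class TestSignificance:
    def _fit(self, rng):
        data, _, _ = random_dataset(rng, D=43, q0=1, q1=4)
        return fit_mm(data), data

    def test_zero_estimate_never_significant(self, rng):
        fit, data = self._fit(rng)
        fit.theta_hat.beta[1] = 0.0
        cov = np.eye(data.p + 1) * 0.04
        table = significance_test(fit, cov, D=data.D, alpha=0.1)
        assert not table["significant"].iloc[1]
        assert table["p_value"].iloc[1] == pytest.approx(1.0)

    def test_large_t_statistic_significant(self, rng):
        fit, data = self._fit(rng)
        sd = 0.05
        fit.theta_hat.beta[2] = 10 * sd
        cov = np.eye(data.p + 1) * sd ** 2
        table = significance_test(fit, cov, D=data.D, alpha=0.1)
        assert table["significant"].iloc[2]

    def test_ci_width_matches_t_table(self, rng):
        """alpha = 0.1, D - p = 38: the critical value is t_{38,0.95} = 1.686."""
        fit, data = self._fit(rng)
        sd = 0.2
        cov = np.eye(data.p + 1) * sd ** 2
        table = significance_test(fit, cov, D=data.D, alpha=0.1)
        width = table["ci_high"] - table["ci_low"]
        np.testing.assert_allclose(width, 2 * 1.686 * sd, rtol=5e-4)

    def test_alpha_validated(self, rng):
        fit, data = self._fit(rng)
        with pytest.raises(ValueError):
            significance_test(fit, np.eye(data.p + 1), D=data.D, alpha=1.5)


def test_draw_counts_moments(rng):
    """Model simulation reproduces the closed-form marginal mean."""
    data, theta, _ = random_dataset(rng, D=5, nu=300.0)
    m1 = marginal_mean(theta, data)
    ys = np.array([draw_counts(theta, data, child_seed(900, i))[0]
                   for i in range(4000)])
    se = ys.std(axis=0) / np.sqrt(ys.shape[0])
    assert np.all(np.abs(ys.mean(axis=0) - m1) <= 4 * se)
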
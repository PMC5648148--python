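"""Likelihood, priors and closed-form tempered conditionals."""

import numpy as np
import pytest
from scipy import stats

from _oracles import grid_moments
from smcdeconv.model import (
    ExpressionMatrix,
    ParticleState,
    PriorSpec,
    TemperatureSchedule,
    conditional_lambda_params,
    conditional_m_params,
    conditional_x_params,
    default_priors,
    incremental_log_weight,
    log_likelihood,
    log_prior,
    log_unnormalized_target,
    partial_mixture,
    sample_prior,
)

LOG_2PI = np.log(2 * np.pi)


def _scalar_instance(y, xm, lam):
    Y = ExpressionMatrix.from_values([[y]])
    x = np.array([[xm]])
    m = np.array([[1.0]])
    return Y, ParticleState(X=x, M=m, lam=lam)


class TestLogLikelihood:
    def test_zero_residual(self, rng):
        X = rng.uniform(1, 2, (4, 2))
        M = rng.dirichlet(np.ones(2), 3).T
        Y = ExpressionMatrix.from_values(X @ M)
        theta = ParticleState(X=X, M=M, lam=1.0)
        assert log_likelihood(Y, theta) == pytest.approx(-(4 * 3 / 2) * LOG_2PI)

    def test_scalar_closed_form(self):
        Y, theta = _scalar_instance(y=2.0, xm=1.0, lam=2.0)
        assert log_likelihood(Y, theta) == pytest.approx(0.5 * np.log(2 / (2 * np.pi)) - 1.0)

    def test_monotone_in_residual(self, rng):
        X = rng.uniform(1, 2, (4, 2))
        M = rng.dirichlet(np.ones(2), 3).T
        truth = X @ M
        resid = rng.standard_normal(truth.shape)
        theta = ParticleState(X=X, M=M, lam=1.0)
        ll1 = log_likelihood(ExpressionMatrix.from_values(truth + resid), theta)
        ll2 = log_likelihood(ExpressionMatrix.from_values(truth + 2 * resid), theta)
        assert ll2 < ll1

    def test_label_switch_invariance(self, rng):
        X = rng.uniform(1, 2, (5, 3))
        M = rng.dirichlet(np.ones(3), 4).T
        Y = ExpressionMatrix.from_values(X @ M + 0.1)
        perm = [2, 0, 1]
        a = log_likelihood(Y, ParticleState(X=X, M=M, lam=1.5))
        b = log_likelihood(Y, ParticleState(X=X[:, perm], M=M[perm, :], lam=1.5))
        assert a == pytest.approx(b, rel=1e-12)

    def test_rejects_bad_shapes_and_lambda(self, tiny_problem):
        Y, theta, _ = tiny_problem
        with pytest.raises(ValueError):
            log_likelihood(ExpressionMatrix.from_values(np.ones((5, 2))), theta)
        with pytest.raises(ValueError):
            ParticleState(X=theta.X, M=theta.M, lam=-1.0)


class TestTemperedTarget:
    def test_eps_zero_is_prior(self, tiny_problem):
        Y, theta, priors = tiny_problem
        assert log_unnormalized_target(theta, Y, 0.0, priors) == pytest.approx(
            log_prior(theta, priors)
        )

    def test_eps_one_is_prior_plus_likelihood(self, tiny_problem):
        Y, theta, priors = tiny_problem
        assert log_unnormalized_target(theta, Y, 1.0, priors) == pytest.approx(
            log_prior(theta, priors) + log_likelihood(Y, theta)
        )

    def test_scalar_instance_matches_independent_sum(self):
        # independently coded scalar evaluation of all density terms
        Y, theta = _scalar_instance(y=1.3, xm=0.8, lam=1.7)
        priors = PriorSpec(
            mu_x=[[0.5]], nu_x=[[2.0]], mu_m=[[1.0]], nu_m=[[4.0]],
            alpha=2.0, beta=3.0,
        )
        eps = 0.6
        expected = (
            stats.gamma.logpdf(1.7, a=2.0, scale=1 / 3.0)
            + stats.norm.logpdf(0.8, 0.5, 1 / np.sqrt(2.0))
            + stats.norm.logpdf(1.0, 1.0, 1 / np.sqrt(4.0))
            + eps * stats.norm.logpdf(1.3, 0.8 * 1.0, 1 / np.sqrt(1.7))
        )
        assert log_unnormalized_target(theta, Y, eps, priors) == pytest.approx(expected)


class TestPartialMixture:
    def test_single_type_empty_sum(self):
        theta = ParticleState(X=[[2.0]], M=[[0.7]], lam=1.0)
        assert partial_mixture(theta, 0, 0, 0) == 0.0

    def test_two_type_arithmetic(self):
        theta = ParticleState(X=[[1.0, 3.0]], M=[[0.5], [0.5]], lam=1.0)
        assert partial_mixture(theta, 0, 0, 0) == pytest.approx(1.5)

    def test_identity_with_full_mixture(self, rng):
        theta = ParticleState(
            X=rng.uniform(0, 2, (3, 3)), M=rng.uniform(0, 1, (3, 2)), lam=1.0
        )
        full = theta.X @ theta.M
        for i in range(3):
            for j in range(2):
                for k in range(3):
                    assert partial_mixture(theta, i, j, k) == pytest.approx(
                        full[i, j] - theta.X[i, k] * theta.M[k, j], abs=1e-12
                    )

    def test_index_error(self):
        theta = ParticleState(X=[[1.0]], M=[[1.0]], lam=1.0)
        with pytest.raises(IndexError):
            partial_mixture(theta, 1, 0, 0)


class TestConditionals:
    def test_prior_limit_m(self, tiny_problem):
        Y, theta, priors = tiny_problem
        mean, var = conditional_m_params(Y, theta, 1, 0, 0.0, priors)
        assert mean == priors.mu_m[1, 0]
        assert var == 1.0 / priors.nu_m[1, 0]

    def test_prior_limit_x(self, tiny_problem):
        Y, theta, priors = tiny_problem
        mean, var = conditional_x_params(Y, theta, 2, 1, 0.0, priors)
        assert mean == priors.mu_x[2, 1]
        assert var == 1.0 / priors.nu_x[2, 1]

    def test_prior_limit_lambda(self, tiny_problem):
        Y, theta, priors = tiny_problem
        assert conditional_lambda_params(Y, theta, 0.0, priors) == (
            priors.alpha, priors.beta,
        )

    def test_m_hand_computed_instance(self):
        # I=2, K=1, J=1, y=(1,2), x=(1,1), lam=1, eps=1 -> U=3, V=3
        Y = ExpressionMatrix.from_values([[1.0], [2.0]])
        theta = ParticleState(X=[[1.0], [1.0]], M=[[0.3]], lam=1.0)
        priors = PriorSpec(
            mu_x=np.zeros((2, 1)), nu_x=np.ones((2, 1)),
            mu_m=[[0.0]], nu_m=[[1.0]], alpha=1.0, beta=1.0,
        )
        mean, var = conditional_m_params(Y, theta, 0, 0, 1.0, priors)
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(1.0 / 3.0)

    def test_lambda_scalar_instance(self):
        Y, theta = _scalar_instance(y=3.0, xm=1.0, lam=1.0)
        priors = PriorSpec(
            mu_x=[[0.0]], nu_x=[[1.0]], mu_m=[[0.0]], nu_m=[[1.0]],
            alpha=1.0, beta=1.0,
        )
        shape, rate = conditional_lambda_params(Y, theta, 1.0, priors)
        assert shape == pytest.approx(1.5)
        assert rate == pytest.approx(3.0)

    def test_x_m_transposed_symmetry(self, rng):
        # swapping the roles of X/M on a transposed instance swaps the formulas
        I = J = 2
        K = 2
        X = rng.uniform(0.5, 1.5, (I, K))
        M = rng.uniform(0.1, 0.9, (K, J))
        Yv = rng.uniform(0.5, 2.5, (I, J))
        pr = PriorSpec(
            mu_x=rng.uniform(0, 1, (I, K)), nu_x=rng.uniform(1, 2, (I, K)),
            mu_m=rng.uniform(0, 1, (K, J)), nu_m=rng.uniform(1, 2, (K, J)),
            alpha=1.0, beta=1.0,
        )
        pr_T = PriorSpec(
            mu_x=pr.mu_m.T, nu_x=pr.nu_m.T, mu_m=pr.mu_x.T, nu_m=pr.nu_x.T,
            alpha=1.0, beta=1.0,
        )
        Y = ExpressionMatrix.from_values(Yv)
        Y_T = ExpressionMatrix.from_values(Yv.T)
        theta = ParticleState(X=X, M=M, lam=1.3)
        theta_T = ParticleState(X=M.T, M=X.T, lam=1.3)
        for k in range(K):
            for j in range(J):
                a = conditional_m_params(Y, theta, k, j, 0.7, pr)
                b = conditional_x_params(Y_T, theta_T, j, k, 0.7, pr_T)
                assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("eps", [0.3, 1.0])
    def test_m_conditional_matches_grid_oracle(self, tiny_problem, eps):
        Y, theta, priors = tiny_problem
        k, j = 0, 1

        def logf(v):
            th = theta.copy()
            th.M[k, j] = v
            return log_unnormalized_target(th, Y, eps, priors)

        mean, var = conditional_m_params(Y, theta, k, j, eps, priors)
        sd = np.sqrt(var)
        gmean, gvar = grid_moments(logf, mean - 15 * sd, mean + 15 * sd)
        assert gmean == pytest.approx(mean, rel=1e-6, abs=1e-9)
        assert gvar == pytest.approx(var, rel=1e-6)

    @pytest.mark.parametrize("eps", [0.3, 1.0])
    def test_x_conditional_matches_grid_oracle(self, tiny_problem, eps):
        Y, theta, priors = tiny_problem
        i, k = 2, 1

        def logf(v):
            th = theta.copy()
            th.X[i, k] = v
            return log_unnormalized_target(th, Y, eps, priors)

        mean, var = conditional_x_params(Y, theta, i, k, eps, priors)
        sd = np.sqrt(var)
        gmean, gvar = grid_moments(logf, mean - 15 * sd, mean + 15 * sd)
        assert gmean == pytest.approx(mean, rel=1e-6, abs=1e-9)
        assert gvar == pytest.approx(var, rel=1e-6)

    def test_lambda_conditional_matches_grid_oracle(self, tiny_problem):
        Y, theta, priors = tiny_problem
        eps = 1.0

        def logf(v):
            th = theta.copy()
            th.lam = v
            return log_unnormalized_target(th, Y, eps, priors)

        shape, rate = conditional_lambda_params(Y, theta, eps, priors)
        mean, var = shape / rate, shape / rate**2
        sd = np.sqrt(var)
        gmean, gvar = grid_moments(logf, max(mean - 15 * sd, 1e-9), mean + 25 * sd,
                                   n=40001)
        assert gmean == pytest.approx(mean, rel=1e-6)
        assert gvar == pytest.approx(var, rel=1e-6)

    def test_lambda_gamma_draw_mean(self, tiny_problem, rng):
        Y, theta, priors = tiny_problem
        shape, rate = conditional_lambda_params(Y, theta, 0.8, priors)
        draws = rng.gamma(shape, 1 / rate, size=200_000)
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se


class TestIncrementalWeight:
    def test_zero_step(self, tiny_problem):
        Y, theta, _ = tiny_problem
        assert incremental_log_weight(theta, Y, 0.4, 0.4) == 0.0

    def test_full_step_is_likelihood(self, tiny_problem):
        Y, theta, _ = tiny_problem
        assert incremental_log_weight(theta, Y, 1.0, 0.0) == pytest.approx(
            log_likelihood(Y, theta)
        )

    def test_scalar_half_step(self):
        Y, theta = _scalar_instance(y=0.0, xm=0.0, lam=1.0)
        # half the single-point log-likelihood (1/2) log(1/(2 pi))
        assert incremental_log_weight(theta, Y, 0.5, 0.0) == pytest.approx(
            0.5 * 0.5 * np.log(1 / (2 * np.pi))
        )

    def test_order_violation(self, tiny_problem):
        Y, theta, _ = tiny_problem
        with pytest.raises(ValueError):
            incremental_log_weight(theta, Y, 0.2, 0.5)

    def test_equals_target_log_difference(self, tiny_problem, rng):
        # (eps_t - eps_prev) * loglik == log Psi_t - log Psi_{t-1} at theta_prev
        Y, theta, priors = tiny_problem
        for _ in range(20):
            e0, e1 = np.sort(rng.uniform(0, 1, 2))
            th = ParticleState(
                X=theta.X + rng.standard_normal(theta.X.shape),
                M=theta.M + rng.standard_normal(theta.M.shape),
                lam=rng.uniform(0.5, 3.0),
            )
            direct = log_unnormalized_target(th, Y, e1, priors) - \
                log_unnormalized_target(th, Y, e0, priors)
            assert abs(incremental_log_weight(th, Y, e1, e0) - direct) <= 1e-10


class TestSamplePrior:
    def test_vanishing_variance_returns_means(self, tiny_problem, rng):
        _, _, priors = tiny_problem
        tight = PriorSpec(
            mu_x=priors.mu_x, nu_x=np.full_like(priors.nu_x, 1e12),
            mu_m=priors.mu_m, nu_m=np.full_like(priors.nu_m, 1e12),
            alpha=priors.alpha, beta=priors.beta,
        )
        th = sample_prior(tight, rng)
        assert np.allclose(th.X, priors.mu_x, atol=1e-4)
        assert np.allclose(th.M, priors.mu_m, atol=1e-4)
        assert th.lam > 0

    def test_reproducible_and_positive(self, tiny_problem):
        _, _, priors = tiny_problem
        a = sample_prior(priors, np.random.default_rng(7))
        b = sample_prior(priors, np.random.default_rng(7))
        assert a.lam == b.lam and np.array_equal(a.X, b.X) and np.array_equal(a.M, b.M)
        assert a.lam > 0

    def test_empirical_mean_of_m(self, tiny_problem, rng):
        _, _, priors = tiny_problem
        n = 100_000
        draws = np.array([sample_prior(priors, rng).M[0, 0] for _ in range(n // 100)])
        # 1000 draws suffice at 3 SE for this check
        se = (priors.nu_m[0, 0] ** -0.5) / np.sqrt(draws.size)
        assert abs(draws.mean() - priors.mu_m[0, 0]) < 3 * se


class TestSchedulesAndTypes:
    def test_schedule_endpoints_enforced(self):
        with pytest.raises(ValueError):
            TemperatureSchedule([0.0, 0.5])
        with pytest.raises(ValueError):
            TemperatureSchedule([0.1, 1.0])
        with pytest.raises(ValueError):
            TemperatureSchedule([0.0, 0.6, 0.4, 1.0])
        assert len(TemperatureSchedule.quadratic(100)) == 100

    def test_expression_matrix_invariants(self):
        with pytest.raises(ValueError):
            ExpressionMatrix([[1.0, np.inf]], ("g1",), ("a", "b"))
        with pytest.raises(ValueError):
            ExpressionMatrix([[1.0], [2.0]], ("g1", "g1"), ("a",))

    def test_default_priors_shapes_and_warning(self):
        Y = ExpressionMatrix.from_values(np.random.default_rng(0).uniform(1, 2, (6, 4)))
        pr = default_priors(Y, 2)
        assert pr.mu_x.shape == (6, 2) and pr.mu_m.shape == (2, 4)
        with pytest.warns(UserWarning):
            default_priors(Y, 5)
        with pytest.raises(ValueError):
            default_priors(Y, 0)
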
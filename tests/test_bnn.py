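import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from fuzzybnn import bnn, cohort as C, mlp


@pytest.fixture(scope="module")
def ridge_toy():
    """1-weight linear observations with known closed-form posterior."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(60, 1))
    y = (1.3 * x[:, 0] + rng.normal(0, 0.5, 60))[:, None]
    alpha, beta = 2.0, 4.0
    model = bnn.LinearModel(1)
    theta = bnn.map_estimate(model, x, y, alpha, beta, np.zeros(1))
    return model, x, y, alpha, beta, theta


def _conjugate(x, y, alpha, beta):
    prec = alpha + beta * float(x[:, 0] @ x[:, 0])
    mean = beta * float(x[:, 0] @ y[:, 0]) / prec
    return mean, 1.0 / np.sqrt(prec)


class TestRegularizedTraining:
    def test_map_matches_ridge_closed_form(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        mean, _ = _conjugate(x, y, alpha, beta)
        assert theta[0] == pytest.approx(mean, rel=1e-6)

    def test_huge_alpha_shrinks_weights_to_zero(self, small_cohort):
        params, _ = bnn.regularized_train(small_cohort, alpha=1e8, beta=1.0,
                                          config=mlp.TrainConfig(seed=0))
        for arr in (params.a, params.U, params.b, params.V):
            assert np.abs(arr).max() < 1e-3

    def test_alpha_zero_reduces_to_unregularized_objective(self):
        # at the unpenalized optimum the data-misfit gradient itself vanishes
        rng = np.random.default_rng(1)
        model = bnn.LinearModel(2)
        x = rng.normal(size=(40, 2))
        y = (x @ np.array([0.5, -1.0]))[:, None]
        theta = bnn.map_estimate(model, x, y, alpha=0.0, beta=3.0,
                                 theta0=np.zeros(2))
        _, g = model.misfit_grad(theta, x, y)
        assert np.abs(g).max() < 1e-5

    def test_mlp_map_training_runs_on_cohort(self, small_cohort):
        params, model = bnn.regularized_train(small_cohort, alpha=0.1, beta=10.0,
                                              config=mlp.TrainConfig(seed=2))
        assert params.shape == (30, 11, 5)
        assert np.isfinite(model.flatten(params)).all()


class TestLogLikelihood:
    def test_zero_residual_unit_noise(self):
        model = bnn.LinearModel(1)
        x = np.ones((4, 1))
        y = model.predict(np.array([2.0]), x)
        ll = bnn.log_likelihood(np.array([2.0]), model, x, y, beta=1.0)
        assert ll == pytest.approx(4 * np.log(1 / np.sqrt(2 * np.pi)))

    def test_duplicating_data_doubles_log_likelihood(self):
        rng = np.random.default_rng(2)
        model = bnn.LinearModel(2)
        theta = np.array([0.3, -0.7])
        x = rng.normal(size=(10, 2))
        y = model.predict(theta, x) + rng.normal(0, 0.5, (10, 1))
        ll1 = bnn.log_likelihood(theta, model, x, y, beta=2.0)
        ll2 = bnn.log_likelihood(theta, model, np.vstack([x, x]),
                                 np.vstack([y, y]), beta=2.0)
        assert ll2 == pytest.approx(2 * ll1)

    def test_matches_hand_computed_gaussian_sum(self):
        model = bnn.LinearModel(1)
        theta = np.array([1.0])
        x = np.array([[1.0], [2.0], [3.0]])
        y = np.array([[1.2], [1.8], [3.5]])
        beta = 4.0
        expected = sum(norm.logpdf(yi, mu, 1 / np.sqrt(beta))
                       for yi, mu in zip(y[:, 0], x[:, 0]))
        assert bnn.log_likelihood(theta, model, x, y, beta) == pytest.approx(expected)


class TestLaplacePosterior:
    def test_sd_matches_conjugate_closed_form(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        post = bnn.laplace_posterior(theta, model, x, y, alpha, beta)
        _, sd = _conjugate(x, y, alpha, beta)
        assert post.sd[0] == pytest.approx(sd, rel=1e-9)
        assert post.mean[0] == theta[0]

    def test_rejects_non_stationary_point(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        with pytest.raises(ValueError, match="optimum"):
            bnn.laplace_posterior(theta + 5.0, model, x, y, alpha, beta)

    def test_posterior_width_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(3)
        model = bnn.LinearModel(1)
        alpha, beta = 1e-6, 4.0     # likelihood-dominated regime
        sds = []
        for n in (200, 800):
            x = rng.normal(size=(n, 1))
            y = (0.5 * x[:, 0] + rng.normal(0, 0.5, n))[:, None]
            theta = bnn.map_estimate(model, x, y, alpha, beta, np.zeros(1))
            sds.append(bnn.laplace_posterior(theta, model, x, y, alpha, beta).sd[0])
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.2)

    def test_prior_only_limit(self):
        model = bnn.LinearModel(1)
        x = np.zeros((5, 1))        # data carry no information about the weight
        y = np.zeros((5, 1))
        alpha = 1e4
        post = bnn.laplace_posterior(np.zeros(1), model, x, y, alpha, beta=1.0)
        assert post.sd[0] == pytest.approx(1 / np.sqrt(alpha), rel=1e-9)


class TestPosteriorPredictive:
    def test_point_mass_posterior_collapses_to_forward_pass(self, small_cohort):
        params, model = bnn.regularized_train(small_cohort, alpha=0.1, beta=10.0,
                                              config=mlp.TrainConfig(seed=4))
        theta = model.flatten(params)
        post = bnn.WeightPosterior(mean=theta, sd=np.full(theta.size, 1e-12),
                                   alpha=0.1, beta=10.0, model=model)
        x = small_cohort.X[0]
        pred = bnn.posterior_predictive(x, post, n_draws=200, seed=0)
        f = model.predict(theta, x[None, :])[0]
        expected = np.exp(10.0 * (f - f.max()))
        expected /= expected.sum()
        np.testing.assert_allclose(pred.mass, expected, atol=1e-6)

    def test_predictive_mean_matches_grid_quadrature(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        post = bnn.laplace_posterior(theta, model, x, y, alpha, beta)
        x_new = np.array([0.7])
        pred = bnn.posterior_predictive(x_new, post, n_draws=20000, seed=1)
        # quadrature of the predictive mean over the exact Gaussian posterior
        mean, sd = _conjugate(x, y, alpha, beta)
        ws = np.linspace(mean - 8 * sd, mean + 8 * sd, 4001)
        dens = norm.pdf(ws, mean, sd)
        expected = np.trapezoid(0.7 * ws * dens, ws) / np.trapezoid(dens, ws)
        assert pred.mean() == pytest.approx(expected, abs=4 * sd * 0.7 / np.sqrt(20000) + 1e-3)

    def test_predictive_variance_exceeds_map_variance(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        post = bnn.laplace_posterior(theta, model, x, y, alpha, beta)
        x_new = np.array([1.5])
        grid = np.linspace(-3, 7, 2001)
        spread = bnn.posterior_predictive(x_new, post, 5000, seed=2, grid=grid)
        point = bnn.WeightPosterior(mean=theta, sd=np.full(1, 1e-12),
                                    alpha=alpha, beta=beta, model=model)
        collapsed = bnn.posterior_predictive(x_new, point, 5000, seed=2, grid=grid)
        assert spread.variance() >= collapsed.variance() - 1e-6

    def test_predictive_variance_monotone_in_widths(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        grid = np.linspace(-5, 8, 2001)

        def var(scale_sd, beta_noise):
            post = bnn.WeightPosterior(
                mean=theta, sd=np.full(1, scale_sd), alpha=alpha,
                beta=beta_noise, model=model)
            return bnn.posterior_predictive(np.array([1.0]), post, 4000,
                                            seed=3, grid=grid).variance()

        assert var(0.3, 4.0) > var(0.05, 4.0)       # wider weight posterior
        assert var(0.1, 1.0) > var(0.1, 16.0)       # lower noise precision

    def test_too_few_draws_rejected(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        post = bnn.laplace_posterior(theta, model, x, y, alpha, beta)
        with pytest.raises(ValueError, match="100"):
            bnn.posterior_predictive(np.array([0.0]), post, n_draws=10)


class TestEvidence:
    def test_matches_exact_marginal_likelihood(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        le = bnn.log_evidence(x, y, model, alpha, beta, theta)
        cov = np.eye(len(y)) / beta + np.outer(x[:, 0], x[:, 0]) / alpha
        exact = multivariate_normal.logpdf(y[:, 0], mean=np.zeros(len(y)), cov=cov)
        assert le == pytest.approx(exact, rel=1e-9)

    def test_noise_predictors_lower_evidence(self):
        rng = np.random.default_rng(6)
        n, alpha, beta = 80, 1.0, 4.0
        x1 = rng.normal(size=(n, 1))
        y = (0.8 * x1[:, 0] + rng.normal(0, 0.5, n))[:, None]
        x3 = np.column_stack([x1, rng.normal(size=(n, 2))])  # two pure-noise inputs
        m1, m3 = bnn.LinearModel(1), bnn.LinearModel(3)
        t1 = bnn.map_estimate(m1, x1, y, alpha, beta, np.zeros(1))
        t3 = bnn.map_estimate(m3, x3, y, alpha, beta, np.zeros(3))
        assert bnn.log_evidence(x1, y, m1, alpha, beta, t1) > \
            bnn.log_evidence(x3, y, m3, alpha, beta, t3)

    def test_rejects_invalid_hyperparameters(self, ridge_toy):
        model, x, y, alpha, beta, theta = ridge_toy
        with pytest.raises(ValueError):
            bnn.log_evidence(x, y, model, 0.0, beta, theta)


class TestAgainstBayesianLinearRegression:
    def test_tanh_bnn_predictive_mean_near_linear_posterior_mean(self):
        # purely linear generative law: the network's predictive mean should
        # track the conjugate Bayesian linear-regression predictive mean
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=(n, 1))
        y = (0.8 * x[:, 0] + rng.normal(0, 0.3, n))[:, None]
        model = bnn.MLPModel(1, 3, 1)
        p0 = mlp.init_params(1, 3, 1, seed=1)
        alpha, beta = 0.01, 1 / 0.09
        theta = bnn.map_estimate(model, x, y, alpha, beta, model.flatten(p0))
        post = bnn.laplace_posterior(theta, model, x, y, alpha, beta)
        x_new = np.array([0.5])
        pred = bnn.posterior_predictive(x_new, post, 4000, seed=9)
        lin_mean, _ = _conjugate(x, y, alpha, beta)
        assert pred.mean() == pytest.approx(0.5 * lin_mean, abs=0.05)
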
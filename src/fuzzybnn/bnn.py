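"""Bayesian treatment of the perceptron: regularized MAP training, Laplace
weight posteriors, Monte-Carlo posterior predictives, and model evidence.

The regularized objective is the evidence-framework one,

    F(theta) = beta * E_D + alpha * E_W,
    E_D = 1/2 sum_i ||y_i - f(x_i; theta)||^2,   E_W = 1/2 ||theta||^2,

i.e. a Gaussian observation model with noise precision ``beta`` and an
isotropic Gaussian weight prior with precision ``alpha``.  The weight posterior
is approximated by a Laplace/Gauss–Newton Gaussian at the MAP; the posterior
predictive integrates the network output over that Gaussian by Monte Carlo.

The machinery is written against a minimal model interface (predict /
data-misfit gradient / Jacobian) with two implementations: the tanh multilayer
perceptron (the deliverable) and a plain linear map used by closed-form
conjugate oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cohort import Cohort
from .mlp import MLPParams, TrainConfig, init_params, one_hot_gos


class LinearModel:
    """f(x; theta) = x . theta, single output.  Conjugate-oracle workhorse."""

    def __init__(self, n_in: int):
        self.n_params = n_in

    def predict(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) @ theta)[:, None]

    def jacobian(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X)[:, None, :]

    def misfit_grad(self, theta, X, Y):
        R = self.predict(theta, X) - Y
        ed = 0.5 * float(np.sum(R**2))
        return ed, np.atleast_2d(X).T @ R[:, 0]


class MLPModel:
    """Flattened-parameter view of the tanh MLP for MAP/Laplace machinery.

    Parameter vector layout: [a, U.ravel(), b, V.ravel()].  Input
    standardization (center/scale) is held by the model, not the parameters.
    """

    def __init__(self, n_in: int, n_hidden: int = 11, n_out: int = 5,
                 input_center: np.ndarray | None = None,
                 input_scale: np.ndarray | None = None):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.n_params = n_hidden + n_in * n_hidden + n_out + n_hidden * n_out
        self.input_center = input_center
        self.input_scale = input_scale

    # -- parameter packing ------------------------------------------------
    def flatten(self, p: MLPParams) -> np.ndarray:
        return np.concatenate([p.a, p.U.ravel(), p.b, p.V.ravel()])

    def unflatten(self, theta: np.ndarray) -> MLPParams:
        I, H, K = self.n_in, self.n_hidden, self.n_out
        i = 0
        a = theta[i:i + H]; i += H
        U = theta[i:i + I * H].reshape(I, H); i += I * H
        b = theta[i:i + K]; i += K
        V = theta[i:i + H * K].reshape(H, K)
        return MLPParams(a.copy(), U.copy(), b.copy(), V.copy(),
                         None if self.input_center is None else self.input_center.copy(),
                         None if self.input_scale is None else self.input_scale.copy())

    def _z(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.input_center is not None:
            return (X - self.input_center) / self.input_scale
        return X

    # -- model interface ---------------------------------------------------
    def predict(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        p = self.unflatten(theta)
        Z = self._z(X)
        H = np.tanh(p.a + Z @ p.U)
        return p.b + H @ p.V

    def misfit_grad(self, theta: np.ndarray, X: np.ndarray, Y: np.ndarray):
        """(E_D, dE_D/dtheta) by backprop; E_D = 1/2 sum of squared residuals."""
        p = self.unflatten(theta)
        Z = self._z(X)
        H = np.tanh(p.a + Z @ p.U)
        F = p.b + H @ p.V
        R = F - Y
        ed = 0.5 * float(np.sum(R**2))
        gb = R.sum(axis=0)
        gV = H.T @ R
        dH = (R @ p.V.T) * (1.0 - H**2)
        ga = dH.sum(axis=0)
        gU = Z.T @ dH
        return ed, np.concatenate([ga, gU.ravel(), gb, gV.ravel()])

    def jacobian(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        """J[i, k, :] = d f_k(x_i) / d theta, shape (n, K, P)."""
        p = self.unflatten(theta)
        Z = self._z(X)
        n = Z.shape[0]
        I, Hn, K = self.n_in, self.n_hidden, self.n_out
        H = np.tanh(p.a + Z @ p.U)
        S = 1.0 - H**2                            # (n, H)
        J = np.zeros((n, K, self.n_params))
        VS = p.V.T[None, :, :] * S[:, None, :]    # (n, K, H): v_jk * s_j
        i0 = 0
        J[:, :, i0:i0 + Hn] = VS; i0 += Hn
        # dU block: v_jk * s_j * z_i  -> (n, K, I*H)
        J[:, :, i0:i0 + I * Hn] = (
            Z[:, None, :, None] * VS[:, :, None, :]).reshape(n, K, I * Hn)
        i0 += I * Hn
        J[:, :, i0:i0 + K] = np.eye(K)[None]; i0 += K
        J[:, :, i0:] = _v_block(H, K)
        return J


def _v_block(H: np.ndarray, K: int) -> np.ndarray:
    """d f_k / d V_jk' = h_j if k == k' else 0, flattened over (j, k')."""
    n, Hn = H.shape
    block = np.zeros((n, K, Hn, K))
    for k in range(K):
        block[:, k, :, k] = H
    return block.reshape(n, K, Hn * K)


@dataclass
class WeightPosterior:
    mean: np.ndarray              # flattened MAP
    sd: np.ndarray                # per-weight posterior SD
    cov: np.ndarray = field(repr=False, default=None)
    alpha: float = 1.0
    beta: float = 1.0
    model: object = None
    gn_fallback: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if np.any(self.sd <= 0):
            raise ValueError("posterior sds must be > 0")

    def draw(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        if self.cov is not None:
            L = np.linalg.cholesky(self.cov)
            return self.mean + rng.standard_normal((n_draws, self.mean.size)) @ L.T
        return self.mean + rng.standard_normal((n_draws, self.mean.size)) * self.sd


@dataclass
class PredictiveDistribution:
    grid: np.ndarray     # outcome values (GOS 1..5 or latent reals)
    mass: np.ndarray     # probability mass per grid point, sums to 1
    draws: np.ndarray = field(repr=False, default=None)   # per-draw network outputs
    kind: str = "ordinal"

    def __post_init__(self) -> None:
        if not np.isclose(self.mass.sum(), 1.0, atol=1e-9):
            raise ValueError("predictive mass must sum to 1")

    def mean(self) -> float:
        return float(np.sum(self.grid * self.mass))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum(self.mass * (self.grid - m) ** 2))


def map_estimate(model, X: np.ndarray, Y: np.ndarray, alpha: float, beta: float,
                 theta0: np.ndarray, maxiter: int = 6000) -> np.ndarray:
    """Minimize beta*E_D + alpha*E_W with L-BFGS from theta0."""
    if beta <= 0 or alpha < 0:
        raise ValueError("need beta > 0 and alpha >= 0")

    def fg(theta):
        ed, ged = model.misfit_grad(theta, X, Y)
        f = beta * ed + 0.5 * alpha * float(theta @ theta)
        g = beta * ged + alpha * theta
        return f, g

    res = minimize(fg, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise FloatingPointError("regularized training diverged")
    return res.x


def regularized_train(cohort: Cohort, alpha: float, beta: float,
                      config: TrainConfig | None = None):
    """MAP-train the tanh MLP on one-hot GOS targets; returns (MLPParams, MLPModel)."""
    config = config or TrainConfig()
    X = cohort.X
    Y = one_hot_gos(cohort.gos)
    center = X.mean(axis=0) if config.standardize else None
    scale = (np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
             if config.standardize else None)
    model = MLPModel(X.shape[1], config.n_hidden, Y.shape[1], center, scale)
    p0 = init_params(X.shape[1], config.n_hidden, Y.shape[1], seed=config.seed)
    theta = map_estimate(model, X, Y, alpha, beta, model.flatten(p0))
    return model.unflatten(theta), model


def log_likelihood(theta: np.ndarray, model, X: np.ndarray, Y: np.ndarray,
                   beta: float) -> float:
    """Gaussian log likelihood sum_i log p(y_i | x_i, theta) at noise precision beta."""
    R = model.predict(theta, X) - np.atleast_2d(Y)
    N = R.size
    return float(0.5 * N * np.log(beta / (2 * np.pi)) - 0.5 * beta * np.sum(R**2))


def _gn_hessian(model, theta, X, alpha, beta) -> np.ndarray:
    J = model.jacobian(theta, X)              # (n, K, P)
    Jf = J.reshape(-1, J.shape[-1])
    return beta * (Jf.T @ Jf) + alpha * np.eye(J.shape[-1])


def laplace_posterior(theta_map: np.ndarray, model, X: np.ndarray, Y: np.ndarray,
                      alpha: float, beta: float,
                      stationarity_tol: float = 0.1) -> WeightPosterior:
    """Gaussian posterior at the MAP with Gauss–Newton curvature.

    Requires theta_map to be (approximately) a stationary point of the
    regularized objective.  Stationarity is judged by the Newton decrement
    g' H^-1 g (the curvature-metric size of the remaining step), which is
    scale-invariant, unlike a raw gradient norm.
    """
    ed, ged = model.misfit_grad(theta_map, X, np.atleast_2d(Y))
    g = beta * ged + alpha * theta_map
    H = _gn_hessian(model, theta_map, X, alpha, beta)
    decrement = float(g @ np.linalg.solve(H, g))
    if decrement > stationarity_tol * max(1.0, np.sqrt(g.size)):
        raise ValueError(
            "theta_map is not at a local optimum "
            f"(Newton decrement {decrement:.3g} too large)")
    fallback = False
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        # Gauss-Newton curvature is PSD; jitter restores positive definiteness
        H = H + 1e-8 * np.trace(H) / H.shape[0] * np.eye(H.shape[0])
        L = np.linalg.cholesky(H)
        fallback = True
    Linv = np.linalg.solve(L, np.eye(L.shape[0]))
    cov = Linv.T @ Linv
    return WeightPosterior(mean=np.asarray(theta_map, float),
                           sd=np.sqrt(np.diag(cov)), cov=cov,
                           alpha=alpha, beta=beta, model=model,
                           gn_fallback=fallback)


def posterior_predictive(x_new: np.ndarray, posterior: WeightPosterior,
                         n_draws: int = 1000, seed: int = 0,
                         grid: np.ndarray | None = None) -> PredictiveDistribution:
    """Monte-Carlo posterior predictive for one new case.

    Multi-output (ordinal) models: the Gaussian observation model restricted to
    one-hot targets gives p(y=k | f) = softmax(beta * f)_k, averaged over weight
    draws.  Single-output models: a Gaussian mixture over the weight draws,
    discretized on a grid.
    """
    if n_draws < 100:
        raise ValueError("need n_draws >= 100")
    rng = np.random.default_rng(seed)
    model = posterior.model
    thetas = posterior.draw(n_draws, rng)
    x_new = np.atleast_2d(np.asarray(x_new, float))
    F = np.stack([model.predict(t, x_new)[0] for t in thetas])   # (draws, K)
    K = F.shape[1]
    if K > 1:
        logits = posterior.beta * F
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        mass = P.mean(axis=0)
        return PredictiveDistribution(grid=np.arange(1, K + 1, dtype=float),
                                      mass=mass / mass.sum(), draws=F,
                                      kind="ordinal")
    mu = F[:, 0]
    noise_sd = 1.0 / np.sqrt(posterior.beta)
    if grid is None:
        lo = mu.min() - 5 * noise_sd
        hi = mu.max() + 5 * noise_sd
        grid = np.linspace(lo, hi, 801)
    dens = np.exp(-0.5 * ((grid[None, :] - mu[:, None]) / noise_sd) ** 2).mean(axis=0)
    mass = dens / dens.sum()
    return PredictiveDistribution(grid=grid, mass=mass, draws=F, kind="latent")


def log_evidence(X: np.ndarray, Y: np.ndarray, model, alpha: float, beta: float,
                 theta_map: np.ndarray) -> float:
    """Laplace approximation to log p(D) = log int p(D|theta) p(theta) dtheta."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("need alpha, beta > 0")
    Y = np.atleast_2d(Y)
    ed, _ = model.misfit_grad(theta_map, X, Y)
    P = theta_map.size
    N = Y.size
    F = beta * ed + 0.5 * alpha * float(theta_map @ theta_map)
    H = _gn_hessian(model, theta_map, X, alpha, beta)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular Hessian in evidence computation")
    return float(0.5 * N * np.log(beta) - 0.5 * N * np.log(2 * np.pi)
                 + 0.5 * P * np.log(alpha) - F - 0.5 * logdet)
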
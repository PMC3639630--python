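"""From-scratch multilayer perceptron for 5-level outcome prediction.

Architecture: 30 inputs -> 11 tanh hidden units -> 5 linear outputs,

    h_j(x) = tanh(a_j + sum_i u_ij x_i)
    f_k(x) = b_k  + sum_j v_jk h_j(x)

trained by full-batch gradient descent on squared error against one-hot
(reversed) GOS targets, with a seeded 60/40 train/test split.  Variable
importance uses the Garson connection-weight method (per-input share of total
connection strength, summing to 1); discrimination is summarized by a
rank-based AUC on a dichotomized outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cohort import Cohort


@dataclass
class MLPParams:
    a: np.ndarray   # (H,)  hidden biases
    U: np.ndarray   # (I,H) input->hidden weights
    b: np.ndarray   # (K,)  output biases
    V: np.ndarray   # (H,K) hidden->output weights
    input_center: np.ndarray | None = None   # optional input standardization
    input_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, float)
        self.U = np.asarray(self.U, float)
        self.b = np.asarray(self.b, float)
        self.V = np.asarray(self.V, float)
        I, H = self.U.shape
        K = self.b.shape[0]
        if self.a.shape != (H,) or self.V.shape != (H, K):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.a, self.U, self.b, self.V):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite parameters")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.U.shape[0], self.U.shape[1], self.b.shape[0]

    def copy(self) -> "MLPParams":
        return MLPParams(self.a.copy(), self.U.copy(), self.b.copy(), self.V.copy(),
                         None if self.input_center is None else self.input_center.copy(),
                         None if self.input_scale is None else self.input_scale.copy())


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    epochs: int = 500
    train_fraction: float = 0.6
    seed: int = 0
    n_hidden: int = 11
    loss: str = "sse"          # squared error on one-hot targets
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.loss != "sse":
            raise ValueError("only squared-error loss is supported")


def init_params(n_in: int, n_hidden: int, n_out: int, seed: int = 0) -> MLPParams:
    """Normal(0, 1/sqrt(fan_in)) initialization, seeded."""
    rng = np.random.default_rng(seed)
    return MLPParams(
        a=rng.normal(0, 1.0 / np.sqrt(n_in), n_hidden),
        U=rng.normal(0, 1.0 / np.sqrt(n_in), (n_in, n_hidden)),
        b=rng.normal(0, 1.0 / np.sqrt(n_hidden), n_out),
        V=rng.normal(0, 1.0 / np.sqrt(n_hidden), (n_hidden, n_out)),
    )


def _standardized(X: np.ndarray, params: MLPParams) -> np.ndarray:
    if params.input_center is not None:
        return (X - params.input_center) / params.input_scale
    return X


def forward(x: np.ndarray, params: MLPParams) -> np.ndarray:
    """Network outputs f_k(x); accepts a single vector or an (n, I) matrix."""
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.shape[0]:
        raise ValueError(f"expected {params.shape[0]} inputs, got {X.shape[1]}")
    Z = _standardized(X, params)
    H = np.tanh(params.a + Z @ params.U)
    F = params.b + H @ params.V
    return F[0] if single else F


def hidden_activations(x: np.ndarray, params: MLPParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(x, float))
    Z = _standardized(X, params)
    return np.tanh(params.a + Z @ params.U)


def split_train_test(n: int, fraction: float = 0.6, seed: int = 0):
    """Seeded disjoint/exhaustive split; |train| = round-half-up(fraction * n)."""
    if n < 2:
        raise ValueError("need n >= 2 to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def one_hot_gos(gos: np.ndarray, n_out: int = 5) -> np.ndarray:
    Y = np.zeros((len(gos), n_out))
    Y[np.arange(len(gos)), np.asarray(gos, int) - 1] = 1.0
    return Y


def loss_and_grad(params: MLPParams, X: np.ndarray, Y: np.ndarray):
    """Mean squared error over all output entries + analytic gradients."""
    Z = _standardized(X, params)
    n = Z.shape[0]
    A = params.a + Z @ params.U
    H = np.tanh(A)
    F = params.b + H @ params.V
    E = F - Y
    loss = float(np.mean(E**2))
    c = 2.0 / E.size
    gb = c * E.sum(axis=0)
    gV = c * H.T @ E
    dH = (E @ params.V.T) * (1.0 - H**2)
    ga = c * dH.sum(axis=0)
    gU = c * Z.T @ dH
    return loss, (ga, gU, gb, gV)


def train(cohort: Cohort, config: TrainConfig | None = None,
          indices: np.ndarray | None = None):
    """Full-batch gradient descent; returns (params, loss_history).

    ``indices`` restricts training to a subset (e.g. the 60% split); by default
    the whole cohort is used.
    """
    config = config or TrainConfig()
    X = cohort.X if indices is None else cohort.X[indices]
    Y = one_hot_gos(cohort.gos if indices is None else cohort.gos[indices])
    n_in, n_out = X.shape[1], Y.shape[1]
    params = init_params(n_in, config.n_hidden, n_out, seed=config.seed)
    if config.standardize:
        params.input_center = X.mean(axis=0)
        params.input_scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    lr = config.learning_rate
    history = []
    for _ in range(config.epochs):
        loss, (ga, gU, gb, gV) = loss_and_grad(params, X, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (loss is not finite); learning_rate={lr}")
        history.append(loss)
        params.a -= lr * ga
        params.U -= lr * gU
        params.b -= lr * gb
        params.V -= lr * gV
    return params, np.array(history)


def normalized_importance(params: MLPParams, names: list[str] | None = None):
    """Garson connection-weight importance: non-negative shares summing to 1.

    Each hidden unit's input weights are normalized to shares, weighted by the
    unit's total absolute outgoing strength, summed over units, and renormalized
    over inputs.
    """
    absU = np.abs(params.U)            # (I, H)
    absV = np.abs(params.V).sum(axis=1)  # (H,)
    col = absU.sum(axis=0)
    if np.all(col * absV == 0):
        raise ValueError("importance undefined for all-zero weights")
    active = col > 0
    shares = np.zeros_like(absU)
    shares[:, active] = absU[:, active] / col[active]
    raw = shares @ absV
    imp = raw / raw.sum()
    if names is not None:
        return dict(zip(names, imp))
    return imp


def permutation_importance(params: MLPParams, X: np.ndarray, gos: np.ndarray,
                           seed: int = 0, n_repeats: int = 5) -> np.ndarray:
    """Alternative importance: mean loss increase when a column is permuted."""
    Y = one_hot_gos(np.asarray(gos, int))
    base, _ = loss_and_grad(params, X, Y)
    rng = np.random.default_rng(seed)
    deltas = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            loss, _ = loss_and_grad(params, Xp, Y)
            deltas[j] += max(loss - base, 0.0)
    total = deltas.sum()
    return deltas / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])


def predict_severity(X: np.ndarray, params: MLPParams) -> np.ndarray:
    """Scalar risk score: expected outcome level under the output activations.

    Squared-error training against one-hot targets makes the outputs approximate
    class probabilities; they are clipped at 0 and renormalized.  Degenerate
    all-non-positive rows fall back to the argmax grade.
    """
    F = np.atleast_2d(forward(X, params))
    P = np.clip(F, 0.0, None)
    rowsum = P.sum(axis=1)
    grades = np.arange(1, F.shape[1] + 1, dtype=float)
    out = np.where(rowsum > 0,
                   (P @ grades) / np.where(rowsum > 0, rowsum, 1.0),
                   grades[np.argmax(F, axis=1)])
    return out


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
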
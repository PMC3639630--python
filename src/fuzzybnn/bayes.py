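"""Bayesian multivariable linear regression with uninformed or informed priors.

The model mirrors the WinBUGS-era analysis of the 5-level (reversed) outcome:

    y = alpha + X b + eps,   eps ~ Normal(0, sigma^2)
    b_j ~ Normal(m_j, s_j^2)     (uninformed: m=0, s=100; informed: from the
                                  meta-analysis posterior of the log OR)
    alpha ~ Normal(0, 100^2)
    sigma ~ Half-Cauchy(0, 5 * sd(y))

Sampling is Gibbs: the coefficient block is conditionally conjugate (one joint
multivariate-normal draw per iteration), and the noise scale is updated by
slice sampling on log sigma.  Four chains are run; convergence is checked with
split-R-hat.  Per-node summaries follow the WinBUGS output layout (mean, SD,
MC error, 2.5%, median, 97.5%, start, sample) with node names like ``b.AGE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import variables as V
from .cohort import Cohort
from .mcmc import MCMCConfig, rhat, slice_sample
from .meta import MetaPosterior

UNINFORMED_SD = 100.0


@dataclass
class PriorEntry:
    mean: float
    sd: float
    kind: str = "uninformed"   # or "informed"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be > 0")
        if self.kind == "uninformed" and self.sd < 10.0:
            raise ValueError("uninformed priors must have sd >= 10")


@dataclass
class PriorSpec:
    entries: dict[str, PriorEntry]    # keyed by canonical variable name
    intercept: PriorEntry = field(default_factory=lambda: PriorEntry(0.0, UNINFORMED_SD))

    @classmethod
    def uninformed(cls, names: list[str]) -> "PriorSpec":
        return cls({n: PriorEntry(0.0, UNINFORMED_SD) for n in names})

    def for_variable(self, name: str) -> PriorEntry:
        return self.entries[name]


def informed_priors(
    meta_map: dict[str, MetaPosterior],
    names: list[str],
    sd_floor: float = 1e-3,
) -> PriorSpec:
    """Build priors from meta-analysis posteriors of log ORs.

    Variables without a meta-analysis result fall back to the uninformed prior
    (a warning is attached to the spec via the entry kind).
    """
    entries = {}
    for name in names:
        key = V.resolve_name(name)
        if key in {V.resolve_name(k) for k in meta_map}:
            mk = next(k for k in meta_map if V.resolve_name(k) == key)
            mp = meta_map[mk]
            mu = float(np.mean(mp.mu_samples))
            sd = max(float(np.std(mp.mu_samples, ddof=1)), sd_floor)
            entries[name] = PriorEntry(mu, sd, kind="informed")
        else:
            entries[name] = PriorEntry(0.0, UNINFORMED_SD)
    return PriorSpec(entries)


@dataclass
class PosteriorSummary:
    node: str
    mean: float
    sd: float
    mc_error: float
    q2_5: float
    median: float
    q97_5: float
    start: int
    sample: int

    def __post_init__(self) -> None:
        if not (self.q2_5 <= self.median <= self.q97_5):
            raise ValueError(f"{self.node}: quantiles out of order")
        if self.sample <= 0:
            raise ValueError("sample must be > 0")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class BayesFit:
    summaries: list[PosteriorSummary]
    chains: np.ndarray            # (chain, draw, param); params = [alpha, b..., sigma]
    param_names: list[str]
    rhat_max: float
    converged: bool

    def summary(self, node: str) -> PosteriorSummary:
        for s in self.summaries:
            if s.node == node:
                return s
        raise KeyError(node)


def mc_error(samples: np.ndarray, batches: int = 20) -> float:
    """Batch-means Monte-Carlo standard error of the posterior mean."""
    samples = np.asarray(samples, dtype=float).ravel()
    m = samples.size
    if m < batches * 10:
        raise ValueError(f"need at least {batches * 10} samples, got {m}")
    k = m // batches
    means = samples[: k * batches].reshape(batches, k).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(batches))


def _gibbs_chain(
    X: np.ndarray, y: np.ndarray,
    prior_mean: np.ndarray, prior_sd: np.ndarray,
    cauchy_scale: float, sigma_fixed: float | None,
    warmup: int, draws: int, rng: np.random.Generator,
) -> np.ndarray:
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = 1.0 / prior_sd**2

    sigma = sigma_fixed if sigma_fixed is not None else float(np.std(y)) or 1.0
    beta = np.zeros(p)
    out = np.empty((draws, p + 1))

    def log_sigma_target(ls: float) -> float:
        s = np.exp(ls)
        resid = y - X @ beta
        sse = float(resid @ resid)
        # Jacobian of log transform gives +ls; Half-Cauchy prior on sigma
        return (-n * ls - 0.5 * sse / s**2
                - np.log1p((s / cauchy_scale) ** 2) + ls)

    ls = np.log(sigma)
    for it in range(warmup + draws):
        # beta | sigma: joint conjugate normal draw
        A = XtX / sigma**2 + np.diag(prior_prec)
        b = Xty / sigma**2 + prior_mean * prior_prec
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        # sigma | beta: slice sample on log sigma
        if sigma_fixed is None:
            ls = slice_sample(log_sigma_target, ls, rng, w=0.5)
            sigma = float(np.exp(ls))
        if it >= warmup:
            out[it - warmup, :p] = beta
            out[it - warmup, p] = sigma
    return out


def fit_bayes(
    cohort: Cohort,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    outcome: str = "gos",
    sigma_fixed: float | None = None,
) -> BayesFit:
    """Gibbs-sample the posterior and return WinBUGS-layout summaries."""
    mcmc = mcmc or MCMCConfig()
    priors = priors or PriorSpec.uninformed(cohort.column_names)
    missing = [n for n in cohort.column_names if n not in priors.entries]
    if missing:
        raise ValueError(f"priors missing for: {missing}")

    y = cohort.outcome(outcome)
    X = np.column_stack([np.ones(cohort.n), cohort.X])
    prior_mean = np.array([priors.intercept.mean]
                          + [priors.entries[n].mean for n in cohort.column_names])
    prior_sd = np.array([priors.intercept.sd]
                        + [priors.entries[n].sd for n in cohort.column_names])
    cauchy_scale = 5.0 * float(np.std(y))

    rng = np.random.default_rng(seed)
    chains = np.stack([
        _gibbs_chain(X, y, prior_mean, prior_sd, cauchy_scale, sigma_fixed,
                     mcmc.warmup, mcmc.draws,
                     np.random.default_rng(rng.integers(2**31 - 1)))
        for _ in range(mcmc.chains)
    ])

    names = ["alpha"] + [V.node_name(n) for n in cohort.column_names] + ["sigma"]
    rhats = [rhat(chains[:, :, j]) for j in range(chains.shape[2])]
    rhat_max = float(np.max(rhats))

    summaries = []
    for j, node in enumerate(names):
        s = chains[:, :, j].reshape(-1)
        q = np.quantile(s, [0.025, 0.5, 0.975])
        summaries.append(PosteriorSummary(
            node=node,
            mean=float(s.mean()), sd=float(s.std(ddof=1)),
            mc_error=mc_error(s),
            q2_5=float(q[0]), median=float(q[1]), q97_5=float(q[2]),
            start=mcmc.warmup, sample=s.size,
        ))
    return BayesFit(
        summaries=summaries, chains=chains, param_names=names,
        rhat_max=rhat_max, converged=rhat_max < 1.1,
    )
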
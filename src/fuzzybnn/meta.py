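"""Bayesian hierarchical (random-effects) meta-analysis of study log odds ratios.

Model: each study reports an observed log OR ``y_i`` with standard error
``se_i``; study-level true effects are exchangeable,

    y_i     ~ Normal(theta_i, se_i^2)
    theta_i ~ Normal(mu, tau^2)
    mu      ~ Normal(0, 10^2)        (log-OR scale, weakly informative)
    tau     ~ Half-Normal(1)

The per-study effects are marginalized analytically — y_i ~ Normal(mu,
se_i^2 + tau^2) — leaving a 2-D posterior over (mu, tau) sampled with emcee's
affine-invariant ensemble.  The consensus odds ratio is exp(mu); its posterior
is the quantity summarized in the published meta-analysis table.  Conditional
draws of theta_i are reconstructed for shrinkage diagnostics.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .mcmc import MCMCConfig, rhat

MU_PRIOR_SD = 10.0
TAU_PRIOR_SD = 1.0


@dataclass
class StudyEffect:
    study_id: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.study_id}: se must be > 0")


@dataclass
class MetaPosterior:
    or_samples: np.ndarray        # consensus OR = exp(mu), pooled draws
    mu_samples: np.ndarray
    tau_samples: np.ndarray
    theta_samples: np.ndarray     # draws x studies, conditional reconstruction
    study_ids: list[str]
    rhat_mu: float
    rhat_tau: float
    converged: bool
    mu_chains: np.ndarray = field(repr=False, default=None)  # (chain, draw)

    @property
    def summary(self) -> dict:
        return summarize(self)._asdict()


Table3Row = namedtuple("Table3Row", ["mean", "sd", "q2_5", "median", "q97_5"])


def _log_posterior(params: np.ndarray, y: np.ndarray, se2: np.ndarray) -> float:
    mu, tau = params
    if tau <= 0:
        return -np.inf
    v = se2 + tau * tau
    loglik = -0.5 * np.sum(np.log(2 * np.pi * v) + (y - mu) ** 2 / v)
    logprior = (
        -0.5 * (mu / MU_PRIOR_SD) ** 2
        - 0.5 * (tau / TAU_PRIOR_SD) ** 2
    )
    return loglik + logprior


def fit_meta(
    effects: list[StudyEffect],
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    tau_fixed: float | None = None,
) -> MetaPosterior:
    """Sample the consensus-OR posterior.

    ``tau_fixed`` collapses the hierarchy to a fixed-effect model (tau pinned);
    with a single study this reduces to the conjugate normal combination of
    prior and likelihood and is sampled exactly.
    """
    if tau_fixed is None and len(effects) < 2:
        raise ValueError("hierarchical meta-analysis needs at least 2 studies")
    if not effects:
        raise ValueError("no study effects given")
    mcmc = mcmc or MCMCConfig()
    y = np.array([e.log_or for e in effects])
    se2 = np.array([e.se**2 for e in effects])
    ids = [e.study_id for e in effects]
    rng = np.random.default_rng(seed)

    if tau_fixed is not None:
        # conjugate: posterior of mu is Normal
        prec = 1.0 / MU_PRIOR_SD**2 + np.sum(1.0 / (se2 + tau_fixed**2))
        mean = np.sum(y / (se2 + tau_fixed**2)) / prec
        sd = 1.0 / np.sqrt(prec)
        total = mcmc.chains * mcmc.draws
        mu_chains = rng.normal(mean, sd, size=(mcmc.chains, mcmc.draws))
        mu_s = mu_chains.reshape(-1)
        tau_s = np.full(total, tau_fixed)
        r_mu = rhat(mu_chains)
        r_tau = 1.0
    else:
        ndim, nwalk = 2, mcmc.walkers
        steps_keep = int(np.ceil(mcmc.draws / nwalk))
        burn = max(200, mcmc.warmup // 10)  # ensemble steps, not per-walker draws
        chains_mu, chains_tau = [], []
        for c in range(mcmc.chains):
            p0 = np.column_stack([
                rng.normal(np.mean(y), np.std(y) + 0.1, size=nwalk),
                np.abs(rng.normal(0.2, 0.1, size=nwalk)) + 1e-3,
            ])
            sampler = emcee.EnsembleSampler(
                nwalk, ndim, _log_posterior, args=(y, se2))
            sampler.random_state = np.random.RandomState(
                int(rng.integers(2**31 - 1))).get_state()
            sampler.run_mcmc(p0, burn + steps_keep)
            chain = sampler.get_chain(discard=burn)  # (steps, walkers, dim)
            chains_mu.append(chain[:, :, 0].T.reshape(-1))
            chains_tau.append(chain[:, :, 1].T.reshape(-1))
        mu_chains = np.array(chains_mu)
        tau_chains = np.array(chains_tau)
        r_mu = rhat(mu_chains)
        r_tau = rhat(tau_chains)
        mu_s = mu_chains.reshape(-1)
        tau_s = tau_chains.reshape(-1)

    # conditional reconstruction of study effects for shrinkage diagnostics
    tau2 = np.maximum(tau_s, 1e-12) ** 2
    prec_i = 1.0 / se2[None, :] + 1.0 / tau2[:, None]
    mean_i = (y[None, :] / se2[None, :] + mu_s[:, None] / tau2[:, None]) / prec_i
    theta = mean_i + rng.normal(size=mean_i.shape) / np.sqrt(prec_i)

    converged = (r_mu < 1.1) and (r_tau < 1.1)
    return MetaPosterior(
        or_samples=np.exp(mu_s),
        mu_samples=mu_s,
        tau_samples=tau_s,
        theta_samples=theta,
        study_ids=ids,
        rhat_mu=r_mu,
        rhat_tau=r_tau,
        converged=converged,
        mu_chains=mu_chains,
    )


def summarize(posterior: MetaPosterior) -> Table3Row:
    """Five-number consensus-OR summary: mean, SD, 2.5%, median, 97.5%."""
    s = np.asarray(posterior.or_samples)
    if s.size < 1000:
        raise ValueError(f"need >= 1000 post-burn-in samples, got {s.size}")
    q = np.quantile(s, [0.025, 0.5, 0.975])
    return Table3Row(float(s.mean()), float(s.std(ddof=1)), float(q[0]),
                     float(q[1]), float(q[2]))


def simulate_studies(
    k: int,
    consensus_or: float,
    tau: float = 0.15,
    se_range: tuple[float, float] = (0.1, 0.3),
    seed: int = 0,
) -> list[StudyEffect]:
    """Simulate k study-level log ORs from the hierarchical model itself."""
    rng = np.random.default_rng(seed)
    mu = np.log(consensus_or)
    theta = rng.normal(mu, tau, size=k)
    se = rng.uniform(*se_range, size=k)
    y = rng.normal(theta, se)
    return [StudyEffect(f"study_{i+1}", float(y[i]), float(se[i])) for i in range(k)]


def read_effects_csv(path) -> list[StudyEffect]:
    df = pd.read_csv(path)
    required = {"study_id", "log_or", "se"}
    if not required.issubset(df.columns):
        raise ValueError(f"effects CSV needs columns {sorted(required)}")
    return [StudyEffect(str(r.study_id), float(r.log_or), float(r.se))
            for r in df.itertuples()]
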
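"""Shared MCMC plumbing: run configuration, convergence diagnostics, slice sampler."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 2000      # kept draws per chain
    walkers: int = 32      # ensemble samplers only

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError("invalid MCMC configuration")


def rhat(chains: np.ndarray) -> float:
    """Gelman–Rubin split-R-hat for a (chain, draw) array."""
    import arviz  # deferred: heavy import

    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(arviz.rhat(chains))


def slice_sample(logp, x0: float, rng: np.random.Generator,
                 w: float = 1.0, max_steps: int = 50) -> float:
    """One update of Neal's stepping-out slice sampler on a scalar target."""
    y = logp(x0) + np.log(rng.random())
    u = rng.random()
    left, right = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logp(left) < y:
            break
        left -= w
    for _ in range(max_steps):
        if logp(right) < y:
            break
        right += w
    while True:
        x1 = rng.uniform(left, right)
        if logp(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
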
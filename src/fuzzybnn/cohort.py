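"""Seedable synthetic aSAH cohort generator.

The original Tirilazad trial database (n = 3551, 30 clinical predictors, 3-month
Glasgow outcome score) is not publicly deposited.  This module generates cohorts
with the same shape and the statistical structure the downstream pipeline
assumes: independent binary/continuous predictors with documented marginals, a
linear latent outcome with either of the two published coefficient sets as
generating truth, optional heteroscedastic noise, and an ordinal 5-level
outcome.

Outcome coding: the latent outcome is oriented so that HIGHER = WORSE, matching
the sign convention of the published coefficients (harmful predictors have
positive betas).  The stored ``gos`` column is therefore the *reversed* Glasgow
outcome score: 1 = good recovery ... 5 = death.  The conventional scale
(5 = good recovery) is ``6 - gos``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import variables as V

GOS_LEVELS = (1, 2, 3, 4, 5)

#: Marginal probabilities of the reversed-GOS categories used to place the
#: default latent thresholds (good recovery, moderate disability, severe
#: disability, vegetative, death) — a realistic 3-month aSAH outcome mix.
DEFAULT_GOS_MIX = (0.40, 0.25, 0.15, 0.05, 0.15)


@dataclass
class PredictorSpec:
    """Marginal distribution + generative coefficient for one predictor."""

    name: str
    kind: str  # "binary" | "continuous"
    cluster: str
    prevalence: float | None = None
    mean: float | None = None
    sd: float | None = None
    true_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"{self.name}: kind must be binary or continuous")
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        else:
            if self.sd is None or self.sd <= 0 or self.mean is None:
                raise ValueError(f"{self.name}: continuous needs mean and sd > 0")
        if self.cluster not in V.CLUSTER_LABELS:
            raise ValueError(f"{self.name}: unknown cluster {self.cluster!r}")
        expected = V.CLUSTER.get(self.name)
        if expected is not None and expected != self.cluster:
            raise ValueError(
                f"{self.name}: cluster {self.cluster!r} conflicts with the fixed "
                f"assignment {expected!r}"
            )

    def marginal_mean(self) -> float:
        return self.prevalence if self.kind == "binary" else self.mean

    def marginal_var(self) -> float:
        if self.kind == "binary":
            return self.prevalence * (1.0 - self.prevalence)
        return self.sd**2


@dataclass
class CohortSpec:
    predictors: list[PredictorSpec]
    n: int = 3551
    intercept: float = 0.0
    noise_sd: float = 1.0
    heteroscedastic: bool = False
    het_variable: str = "Age"
    het_slope: float = 0.5
    gos_thresholds: tuple[float, float, float, float] = (0.0, 1.0, 2.0, 3.0)
    outcome_coding: str = "ordinal_gos"  # or "latent_continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.predictors) != 30:
            raise ValueError(f"expected exactly 30 predictors, got {len(self.predictors)}")
        names = [p.name for p in self.predictors]
        if len(set(names)) != 30:
            raise ValueError("duplicate predictor names")
        t = tuple(self.gos_thresholds)
        if len(t) != 4 or any(t[i] >= t[i + 1] for i in range(3)):
            raise ValueError("gos_thresholds must be 4 strictly ascending reals")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.predictors]

    @property
    def betas(self) -> dict[str, float]:
        return {p.name: p.true_beta for p in self.predictors}

    def latent_moments(self) -> tuple[float, float]:
        """Mean and SD of the latent outcome under independent predictors."""
        m = self.intercept + sum(p.true_beta * p.marginal_mean() for p in self.predictors)
        v = self.noise_sd**2 + sum(p.true_beta**2 * p.marginal_var() for p in self.predictors)
        return m, float(np.sqrt(v))

    def reset_thresholds(self, mix: tuple = DEFAULT_GOS_MIX) -> None:
        """Re-place GOS thresholds at latent quantiles for the given outcome mix.

        Call after editing coefficients or noise so the ordinal coding keeps a
        non-degenerate category mix.
        """
        m, s = self.latent_moments()
        cum = np.cumsum(mix)[:4]
        self.gos_thresholds = tuple(stats.norm.ppf(cum, loc=m, scale=max(s, 1e-9)))


@dataclass
class Cohort:
    X: np.ndarray           # n x 30
    y_latent: np.ndarray    # n
    gos: np.ndarray         # n, reversed GOS in {1..5}
    column_names: list[str] = field(default_factory=lambda: list(V.VARIABLE_NAMES))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y_latent = np.asarray(self.y_latent, dtype=float)
        self.gos = np.asarray(self.gos, dtype=int)
        n = self.X.shape[0]
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("X width does not match column_names")
        if self.y_latent.shape != (n,) or self.gos.shape != (n,):
            raise ValueError("outcome length does not match X")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y_latent).all()):
            raise ValueError("cohort contains non-finite values")
        if not np.isin(self.gos, GOS_LEVELS).all():
            raise ValueError("gos values must lie in 1..5")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def outcome(self, which: str) -> np.ndarray:
        if which == "latent":
            return self.y_latent
        if which == "gos":
            return self.gos.astype(float)
        raise ValueError(f"unknown outcome {which!r}")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df["gos"] = self.gos
        df["y_latent"] = self.y_latent
        return df


def default_spec(
    beta_source: str = "table1",
    n: int = 3551,
    noise_sd: float = 1.0,
    heteroscedastic: bool = False,
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec with the published coefficient set as generating truth.

    ``beta_source`` selects which published multivariable fit supplies the
    generative coefficients ("table1" = frequentist, "table2" = Bayesian
    posterior means); predictors absent from the chosen set get a null effect.
    GOS thresholds are placed at latent-scale quantiles that yield the
    documented outcome mix.
    """
    if beta_source == "table1":
        betas = V.TABLE1_BETAS
    elif beta_source == "table2":
        betas = V.TABLE2_BETAS
    else:
        raise ValueError("beta_source must be 'table1' or 'table2'")

    predictors = []
    for name in V.VARIABLE_NAMES:
        kind = V.KIND[name]
        if kind == "binary":
            p = PredictorSpec(
                name=name, kind=kind, cluster=V.CLUSTER[name],
                prevalence=V.BINARY_PREVALENCE[name],
                true_beta=betas.get(name, 0.0),
            )
        else:
            mu, sd = V.CONTINUOUS_MARGINALS[name]
            p = PredictorSpec(
                name=name, kind=kind, cluster=V.CLUSTER[name],
                mean=mu, sd=sd, true_beta=betas.get(name, 0.0),
            )
        predictors.append(p)

    spec = CohortSpec(
        predictors=predictors, n=n, noise_sd=noise_sd,
        heteroscedastic=heteroscedastic, seed=seed,
    )
    spec.reset_thresholds()
    return spec


def generate(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Sample a cohort; a pure function of (spec, seed)."""
    if spec.n < 50:
        raise ValueError("n < 50 is refused: downstream fits would be degenerate")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    n = spec.n
    X = np.empty((n, 30))
    for j, p in enumerate(spec.predictors):
        if p.kind == "binary":
            X[:, j] = (rng.random(n) < p.prevalence).astype(float)
        else:
            X[:, j] = rng.normal(p.mean, p.sd, size=n)

    beta = np.array([p.true_beta for p in spec.predictors])
    eta = spec.intercept + X @ beta

    scale = np.full(n, spec.noise_sd)
    if spec.heteroscedastic:
        j = spec.names.index(spec.het_variable)
        pj = spec.predictors[j]
        z = (X[:, j] - pj.marginal_mean()) / np.sqrt(pj.marginal_var())
        scale = spec.noise_sd * np.maximum(0.1, 1.0 + spec.het_slope * z)
    y_latent = eta + rng.normal(0.0, 1.0, size=n) * scale

    gos = np.searchsorted(np.asarray(spec.gos_thresholds), y_latent) + 1
    return Cohort(X=X, y_latent=y_latent, gos=gos, column_names=list(spec.names))


def write_csv(cohort: Cohort, path) -> None:
    cohort.frame().to_csv(path, index=False)


def read_csv(path) -> Cohort:
    """Read a cohort CSV (30 predictor columns + gos [+ y_latent])."""
    df = pd.read_csv(path)
    if "gos" not in df.columns:
        raise ValueError("cohort file lacks required 'gos' column")
    names = [c for c in df.columns if c not in ("gos", "y_latent")]
    gos = df["gos"].to_numpy()
    if not np.isin(gos, GOS_LEVELS).all():
        bad = sorted(set(gos) - set(GOS_LEVELS))
        raise ValueError(f"gos values outside 1..5: {bad}")
    if df[names].isna().any().any():
        raise ValueError("cohort file contains missing predictor values")
    y_latent = df["y_latent"].to_numpy() if "y_latent" in df.columns else gos.astype(float)
    return Cohort(X=df[names].to_numpy(float), y_latent=y_latent,
                  gos=gos.astype(int), column_names=names)
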
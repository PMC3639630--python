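"""Frequentist multivariable linear regression with diagnostics.

Mirrors the published analysis: an OLS fit of the 5-level (reversed) Glasgow
outcome score — treated as continuous — on the 30 predictors, with per-predictor
collinearity diagnostics (tolerance, VIF) and a Breusch–Pagan test for
heteroscedasticity.  Logistic odds ratios on a dichotomized outcome are
provided alongside the betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class RegressionResult:
    table: pd.DataFrame          # index = predictor names; beta, se, ci_low, ci_high, p_value, tolerance, vif
    intercept: float
    r2: float
    residuals: np.ndarray
    bp_stat: float
    bp_pvalue: float
    outcome: str

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["tolerance"] * t["vif"], 1.0, atol=1e-9):
            raise ValueError("tolerance * VIF must equal 1")

    def beta(self, name: str) -> float:
        return float(self.table.loc[name, "beta"])

    def se(self, name: str) -> float:
        return float(self.table.loc[name, "se"])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "intercept": self.intercept,
            "r2": self.r2,
            "bp_stat": self.bp_stat,
            "bp_pvalue": self.bp_pvalue,
            "predictors": self.table.reset_index()
                                    .rename(columns={"index": "name"})
                                    .to_dict(orient="records"),
        }


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in exact linear dependence via the QR diagonal
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(len(names)) if j < len(diag) and diag[j] <= tol]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns include: {bad or 'undetermined'}"
        )


def fit_ols(cohort: Cohort, outcome: str = "gos") -> RegressionResult:
    """OLS of the chosen outcome on all predictors, with diagnostics attached."""
    X = cohort.X
    y = cohort.outcome(outcome)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")
    _check_rank(np.column_stack([np.ones(n), X]), ["(intercept)"] + cohort.column_names)

    exog = sm.add_constant(X)
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int(alpha=0.05)

    tol_vif = collinearity(X, cohort.column_names)
    table = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "se": fit.bse[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p_value": fit.pvalues[1:],
            "tolerance": tol_vif["tolerance"].to_numpy(),
            "vif": tol_vif["vif"].to_numpy(),
        },
        index=cohort.column_names,
    )
    bp_stat, bp_p = breusch_pagan(fit.resid, X)
    return RegressionResult(
        table=table,
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        residuals=np.asarray(fit.resid),
        bp_stat=bp_stat,
        bp_pvalue=bp_p,
        outcome=outcome,
    )


def collinearity(X: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Per-variable (tolerance, VIF): VIF_j = 1/(1 - R^2_j) of column j on the rest."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names if names is not None else [f"x{j}" for j in range(p)]
    if np.any(X.std(axis=0) == 0):
        const = [names[j] for j in range(p) if X[:, j].std() == 0]
        raise ValueError(f"constant column(s): {const}")
    vif = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        r2 = min(r2, 1.0 - 1e-12)
        vif[j] = 1.0 / (1.0 - r2)
    vif = np.maximum(vif, 1.0)
    return pd.DataFrame({"tolerance": 1.0 / vif, "vif": vif}, index=names)


def breusch_pagan(residuals: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Breusch–Pagan LM test: n.R^2 of the squared-residual auxiliary regression."""
    residuals = np.asarray(residuals, dtype=float)
    X = np.asarray(X, dtype=float)
    if residuals.shape[0] != X.shape[0]:
        raise ValueError("residuals and X have different lengths")
    if np.allclose(residuals, residuals[0]):
        return 0.0, 1.0
    lm, lm_p, _, _ = het_breuschpagan(residuals, sm.add_constant(X))
    return float(lm), float(lm_p)


@dataclass
class OddsRatioResult:
    table: pd.DataFrame              # or, ci_low, ci_high, p_value per predictor
    dichotomize_at: int
    separation_flag: bool = False
    separated_variables: list[str] = field(default_factory=list)


def odds_ratios(cohort: Cohort, dichotomize_at: int = 2) -> OddsRatioResult:
    """Logistic odds ratios for poor outcome (reversed GOS > cut).

    Default cut 2 splits {good recovery, moderate disability} against the rest.
    Complete separation is flagged rather than estimated.
    """
    y = (cohort.gos > dichotomize_at).astype(float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be non-empty at this cut")
    exog = sm.add_constant(cohort.X)
    try:
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        fit, converged = None, False

    sep_vars: list[str] = []
    if fit is not None:
        big = np.abs(fit.params[1:]) > 15  # implausible log-OR => quasi-separation
        sep_vars = [cohort.column_names[j] for j in np.flatnonzero(big)]
    if fit is None or not converged or sep_vars:
        return OddsRatioResult(
            table=pd.DataFrame(columns=["or", "ci_low", "ci_high", "p_value"]),
            dichotomize_at=dichotomize_at,
            separation_flag=True,
            separated_variables=sep_vars,
        )
    ci = np.exp(fit.conf_int(alpha=0.05))
    table = pd.DataFrame(
        {
            "or": np.exp(fit.params[1:]),
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p_value": fit.pvalues[1:],
        },
        index=cohort.column_names,
    )
    return OddsRatioResult(table=table, dichotomize_at=dichotomize_at)
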
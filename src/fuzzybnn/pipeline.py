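"""End-to-end orchestration of the decision-rule derivation chain.

Stage order is fixed: cohort -> linear regression -> meta-analysis ->
Bayesian regression -> MLP -> Bayesian-regularized network -> fuzzy
inference.  Fuzzy inference is deliberately last and refuses to run unless
the Bayesian network stage ran first: the learning machinery must finish
exploring the posterior before crisp rules are applied.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bayes, bnn, cohort as cohort_mod, fuzzy, linear, meta, mlp
from .mcmc import MCMCConfig

log = logging.getLogger("fuzzybnn.pipeline")

STAGE_ORDER = ("linear", "meta", "bayes", "mlp", "bnn", "fuzzy")

DEFAULT_CONFIG: dict = {
    "cohort": {
        "source": "generate",        # or a CSV path
        "beta_source": "table1",
        "n": 3551,
        "noise_sd": 1.0,
        "heteroscedastic": False,
    },
    "stages": {s: True for s in STAGE_ORDER},
    "seeds": {"cohort": 1, "meta": 2, "bayes": 3, "mlp": 4, "bnn": 5},
    "mcmc": {"chains": 4, "warmup": 1000, "draws": 2000},
    "meta": {"effects_csv": None, "consensus_or": 2.17, "tau": 0.15, "k_studies": 8},
    "mlp": {"learning_rate": 0.05, "epochs": 300, "train_fraction": 0.6,
            "n_hidden": 11},
    "bnn": {"alpha": 0.1, "beta": 10.0},
    "fuzzy": {
        "patients": {
            "worked_example": ["elderly", "coronary artery disease",
                               "hypertensive", "diabetic", "second stroke",
                               "cerebral ischemia", "seizures"],
        },
    },
}


class StageOrderError(RuntimeError):
    pass


class StageError(RuntimeError):
    """A stage failed; the partial report so far is attached."""

    def __init__(self, stage: str, cause: Exception, report: "Report"):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_report = report


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    raw: dict

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(_merge(DEFAULT_CONFIG, doc))

    @classmethod
    def default(cls, **overrides) -> "PipelineConfig":
        return cls(_merge(DEFAULT_CONFIG, overrides))

    def __getitem__(self, key):
        return self.raw[key]


def validate_config(source) -> list[str]:
    """Schema and cross-stage dependency checks; an empty list means valid."""
    if isinstance(source, PipelineConfig):
        cfg = source.raw
    elif isinstance(source, dict):
        cfg = _merge(DEFAULT_CONFIG, source)
    else:
        cfg = PipelineConfig.load(source).raw

    issues: list[str] = []
    co = cfg["cohort"]
    if co.get("source") == "generate":
        if co.get("beta_source") not in ("table1", "table2"):
            issues.append("cohort.beta_source must be 'table1' or 'table2'")
        if int(co.get("n", 0)) < 50:
            issues.append("cohort.n must be >= 50")
        if float(co.get("noise_sd", 1.0)) <= 0:
            issues.append("cohort.noise_sd must be > 0")
    else:
        path = Path(str(co["source"]))
        if not path.exists():
            issues.append(f"cohort.source file not found: {path}")
        else:
            try:
                c = cohort_mod.read_csv(path)
                if c.X.shape[1] != 30:
                    issues.append(
                        f"cohort has {c.X.shape[1]} predictors; the pipeline expects 30")
            except ValueError as exc:
                issues.append(f"cohort.source unreadable: {exc}")
    tf = float(cfg["mlp"].get("train_fraction", 0.6))
    if not 0.0 < tf < 1.0:
        issues.append("mlp.train_fraction must be in (0, 1)")
    if cfg["stages"].get("fuzzy") and not cfg["stages"].get("bnn"):
        issues.append("stages.fuzzy requires stages.bnn: fuzzy rules are applied "
                      "only after the Bayesian network stage")
    if float(cfg["bnn"].get("alpha", 1)) <= 0 or float(cfg["bnn"].get("beta", 1)) <= 0:
        issues.append("bnn.alpha and bnn.beta must be > 0")
    for key in ("chains", "warmup", "draws"):
        if int(cfg["mcmc"].get(key, 1)) < 0:
            issues.append(f"mcmc.{key} must be non-negative")
    return issues


@dataclass
class Report:
    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: str = "1"

    def to_json(self, path=None) -> str:
        doc = {"schema_version": self.schema_version,
               "provenance": self.provenance, "blocks": self.blocks}
        text = json.dumps(doc, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run(config: PipelineConfig | dict | None = None, out_dir=None) -> Report:
    """Execute the enabled stages in order and assemble the report."""
    if config is None:
        config = PipelineConfig.default()
    elif isinstance(config, dict):
        config = PipelineConfig.default(**config)
    cfg = config.raw
    stages = cfg["stages"]
    if stages.get("fuzzy") and not stages.get("bnn"):
        raise StageOrderError(
            "fuzzy stage requires the bnn stage: fuzzy rules are applied only "
            "after Bayesian network formulation")
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))

    seeds = cfg["seeds"]
    report = Report(provenance={"seeds": dict(seeds),
                                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")})
    state: dict = {}
    plan = [("cohort", _run_cohort)]
    plan += [(name, fn) for name, fn in (
        ("linear", _run_linear), ("meta", _run_meta), ("bayes", _run_bayes),
        ("mlp", _run_mlp), ("bnn", _run_bnn), ("fuzzy", _run_fuzzy),
    ) if stages.get(name)]

    for name, fn in plan:
        t0 = time.time()
        log.info("stage %s: starting (seed=%s)", name, seeds.get(name))
        try:
            block = fn(cfg, seeds, state)
        except Exception as exc:
            raise StageError(name, exc, report) from exc
        if block is not None:
            block["duration_s"] = time.time() - t0
            report.blocks[name] = block
        log.info("stage %s: done in %.2fs", name, time.time() - t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
    return report


def _run_cohort(cfg, seeds, state):
    co = cfg["cohort"]
    if co["source"] == "generate":
        spec = cohort_mod.default_spec(
            beta_source=co["beta_source"], n=int(co["n"]),
            noise_sd=float(co["noise_sd"]),
            heteroscedastic=bool(co["heteroscedastic"]))
        coh = cohort_mod.generate(spec, seed=int(seeds["cohort"]))
    else:
        coh = cohort_mod.read_csv(co["source"])
    state["cohort"] = coh
    state["mcmc"] = MCMCConfig(**{k: int(v) for k, v in cfg["mcmc"].items()})
    return {"n": coh.n, "p": coh.X.shape[1],
            "gos_counts": {int(k): int(v) for k, v in
                           zip(*np.unique(coh.gos, return_counts=True))}}


def _run_linear(cfg, seeds, state):
    coh = state["cohort"]
    res = linear.fit_ols(coh, outcome="gos")
    ors = linear.odds_ratios(coh)
    block = res.to_dict()
    block["odds_ratios"] = None if ors.separation_flag else ors.table["or"].to_dict()
    return block


def _run_meta(cfg, seeds, state):
    mco = cfg["meta"]
    if mco.get("effects_csv"):
        effects = meta.read_effects_csv(mco["effects_csv"])
    else:
        effects = meta.simulate_studies(
            int(mco["k_studies"]), float(mco["consensus_or"]),
            tau=float(mco["tau"]), seed=int(seeds["meta"]))
    post = meta.fit_meta(effects, state["mcmc"], seed=int(seeds["meta"]))
    state["meta"] = post
    row = meta.summarize(post)
    return {"consensus_or": row._asdict(), "rhat_mu": post.rhat_mu,
            "converged": post.converged}


def _run_bayes(cfg, seeds, state):
    fit = bayes.fit_bayes(state["cohort"], mcmc=state["mcmc"],
                          seed=int(seeds["bayes"]), outcome="gos")
    state["bayes"] = fit
    return {"summaries": [s.to_dict() for s in fit.summaries],
            "rhat_max": fit.rhat_max, "converged": fit.converged}


def _run_mlp(cfg, seeds, state):
    coh = state["cohort"]
    mcfg = mlp.TrainConfig(seed=int(seeds["mlp"]), **cfg["mlp"])
    tr, te = mlp.split_train_test(coh.n, mcfg.train_fraction, seed=mcfg.seed)
    params, history = mlp.train(coh, mcfg, indices=tr)
    state["mlp"] = params
    imp = mlp.normalized_importance(params, coh.column_names)
    block = {
        "train_n": int(tr.size), "test_n": int(te.size),
        "final_loss": float(history[-1]),
        "importance": {k: float(v) for k, v in imp.items()},
        "importance_sum": float(sum(imp.values())),
    }
    scores = mlp.predict_severity(coh.X[te], params)
    labels = coh.gos[te] > 2
    try:
        block["test_auc"] = mlp.auc(scores, labels)
    except ValueError:
        block["test_auc"] = None
    return block


def _run_bnn(cfg, seeds, state):
    coh = state["cohort"]
    bco = cfg["bnn"]
    bcfg = mlp.TrainConfig(seed=int(seeds["bnn"]),
                           n_hidden=int(cfg["mlp"]["n_hidden"]))
    params, model = bnn.regularized_train(
        coh, float(bco["alpha"]), float(bco["beta"]), bcfg)
    theta = model.flatten(params)
    posterior = bnn.laplace_posterior(
        theta, model, coh.X, mlp.one_hot_gos(coh.gos),
        float(bco["alpha"]), float(bco["beta"]))
    state["bnn"] = posterior
    return {"alpha": float(bco["alpha"]), "beta": float(bco["beta"]),
            "n_params": int(theta.size),
            "max_weight_sd": float(posterior.sd.max()),
            "median_weight_sd": float(np.median(posterior.sd))}


def _run_fuzzy(cfg, seeds, state):
    if "bnn" not in state:
        raise StageOrderError("fuzzy stage requires the bnn stage to have run first")
    coh = state["cohort"]
    rb = fuzzy.default_rule_base()
    classifications = {}
    for label, factors in cfg["fuzzy"]["patients"].items():
        r = fuzzy.classify_case(factors, rule_base=rb)
        classifications[label] = {"crisp_score": r.crisp_score, "label": r.label,
                                  "activations": list(r.activations)}
    # Eq.-7-style defuzzification of the posterior predictive for a median patient
    x_med = np.median(coh.X, axis=0)
    pred = bnn.posterior_predictive(x_med, state["bnn"], n_draws=500,
                                    seed=int(seeds["bnn"]))
    return {"poor_threshold": rb.poor_threshold,
            "classifications": classifications,
            "bnn_defuzz_median_patient": fuzzy.defuzz_bnn(pred)}
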
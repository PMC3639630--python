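"""Fuzzy-logic inference over the three risk-factor clusters.

The 30 predictors partition into demographic (3), systemic (9) and neurologic
(18) clusters.  Three Mamdani rules form a severity ladder over the linguistic
output "suspicion of poor outcome" on a [0, 3] clusters-fulfilled universe:

    R1: demographic fulfilled                          -> low suspicion
    R2: demographic AND systemic fulfilled             -> raised suspicion
    R3: demographic AND systemic AND neurologic        -> high suspicion

Cluster membership is the fraction of the cluster's members present (1 when
all are present).  Because the rules are an ordinal ladder — a patient who
triggers the high-suspicion rule should not also accumulate low-suspicion
evidence — defuzzification applies ordinal-dominance weighting (the most
severe applicable rule retains its activation; weaker rules keep only their
excess) before the usual Mamdani clip / max-aggregate / centroid step.  A
crisp centroid above 2.5 clusters denotes poor prognosis.

``classify_case`` evaluates the rule antecedents on presence-saturating
memberships by default (a cluster counts as engaged once any member is
present, matching the "some members are present" reading of the rules); the
graded fractional antecedent is available via ``antecedent="fraction"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import variables as V

POOR_THRESHOLD = 2.5


@dataclass
class ClusterAssignment:
    mapping: dict[str, str]        # variable name -> cluster label

    def __post_init__(self) -> None:
        sizes = self.sizes
        if (sizes["demographic"], sizes["systemic"], sizes["neurologic"]) != (3, 9, 18):
            raise ValueError(f"cluster sizes must be 3/9/18, got {sizes}")
        if len(self.mapping) != 30:
            raise ValueError("assignment must cover exactly 30 variables")

    @property
    def sizes(self) -> dict[str, int]:
        out = {c: 0 for c in V.CLUSTER_LABELS}
        for c in self.mapping.values():
            out[c] += 1
        return out

    def members(self, cluster: str) -> set[str]:
        return {n for n, c in self.mapping.items() if c == cluster}


def assign_clusters() -> ClusterAssignment:
    """The fixed demographic/systemic/neurologic partition of the 30 variables."""
    return ClusterAssignment(dict(V.CLUSTER))


@dataclass
class MembershipDegrees:
    demographic: float
    systemic: float
    neurologic: float

    def __post_init__(self) -> None:
        for v in (self.demographic, self.systemic, self.neurologic):
            if not 0.0 <= v <= 1.0:
                raise ValueError("membership degrees must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.demographic, self.systemic, self.neurologic)


def memberships(present: set[str] | list[str],
                assignment: ClusterAssignment | None = None) -> MembershipDegrees:
    """Fractional cluster membership: |present ∩ cluster| / |cluster|."""
    assignment = assignment or assign_clusters()
    resolved = {V.resolve_name(name) for name in present}
    unknown = resolved - set(assignment.mapping)
    if unknown:
        raise KeyError(f"variables outside the assignment: {sorted(unknown)}")
    degs = {}
    for c in V.CLUSTER_LABELS:
        members = assignment.members(c)
        degs[c] = len(resolved & members) / len(members)
    return MembershipDegrees(degs["demographic"], degs["systemic"], degs["neurologic"])


@dataclass
class FuzzySet:
    """Piecewise-linear membership function on the output universe."""
    name: str
    points: list[tuple[float, float]]    # (x, mu) vertices, x ascending

    def mu(self, x: np.ndarray) -> np.ndarray:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        return np.interp(x, xs, ys, left=ys[0], right=ys[-1])

    @classmethod
    def triangle(cls, name, a, b, c):
        pts = [(a, 1.0 if a == b else 0.0), (b, 1.0), (c, 1.0 if b == c else 0.0)]
        # collapse duplicate x at degenerate shoulders
        seen, out = set(), []
        for x, y in pts:
            if x not in seen:
                out.append((x, y)); seen.add(x)
        return cls(name, out)

    @classmethod
    def trapezoid(cls, name, a, b, c, d):
        pts = [(a, 0.0), (b, 1.0), (c, 1.0), (d, 0.0 if c != d else 1.0)]
        seen, out = set(), []
        for x, y in pts:
            if x not in seen:
                out.append((x, y)); seen.add(x)
        return cls(name, out)


@dataclass
class FuzzyRuleBase:
    low: FuzzySet
    raised: FuzzySet
    high: FuzzySet
    universe: tuple[float, float] = (0.0, 3.0)
    grid_resolution: int = 2001
    poor_threshold: float = POOR_THRESHOLD

    def grid(self, resolution: int | None = None) -> np.ndarray:
        return np.linspace(*self.universe, resolution or self.grid_resolution)

    def output_sets(self) -> tuple[FuzzySet, FuzzySet, FuzzySet]:
        return (self.low, self.raised, self.high)

    def to_yaml(self, path) -> None:
        doc = {
            "universe": list(self.universe),
            "grid_resolution": self.grid_resolution,
            "poor_threshold": self.poor_threshold,
            "sets": {s.name: [list(p) for p in s.points] for s in self.output_sets()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "FuzzyRuleBase":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sets = {name: FuzzySet(name, [tuple(p) for p in pts])
                for name, pts in doc["sets"].items()}
        return cls(low=sets["low"], raised=sets["raised"], high=sets["high"],
                   universe=tuple(doc["universe"]),
                   grid_resolution=int(doc["grid_resolution"]),
                   poor_threshold=float(doc["poor_threshold"]))


def default_rule_base() -> FuzzyRuleBase:
    """Output sets on the [0, 3] clusters-fulfilled universe.

    Shapes are chosen so that a fully activated high-suspicion set has its
    centroid above the 2.5-cluster poor-prognosis cut-off; they are config
    data, not learned quantities.
    """
    return FuzzyRuleBase(
        low=FuzzySet.triangle("low", 0.0, 0.0, 1.5),
        raised=FuzzySet.triangle("raised", 0.75, 1.5, 2.25),
        high=FuzzySet.trapezoid("high", 1.9, 2.75, 3.0, 3.0),
    )


def rule_activations(m: MembershipDegrees) -> tuple[float, float, float]:
    """Mamdani min-conjunction of the rule ladder: (w_low, w_raised, w_high)."""
    d, s, n = m.as_tuple()
    return (d, min(d, s), min(d, s, n))


@dataclass
class DefuzzResult:
    crisp_score: float | None
    label: str                    # "poor" | "not-poor" | "no-evidence"
    method: str
    activations: tuple[float, float, float]

    @property
    def poor(self) -> bool:
        return self.label == "poor"


_METHODS = ("centroid", "max_min", "left_of_mean", "right_of_mean")


def _crisp(grid: np.ndarray, mu: np.ndarray, method: str,
           integrate: str = "trapezoid") -> float:
    if method == "centroid":
        # trapezoid for a sampled continuous universe; plain weighted mean for
        # a discrete outcome grid (where endpoint half-weights would bias it)
        if integrate == "trapezoid":
            return float(np.trapezoid(grid * mu, grid) / np.trapezoid(mu, grid))
        return float(np.sum(grid * mu) / np.sum(mu))
    peak = mu.max()
    at_max = grid[mu >= peak - 1e-12]
    if method == "max_min":
        return float(at_max.mean())
    if method == "left_of_mean":
        return float(at_max[0])
    if method == "right_of_mean":
        return float(at_max[-1])
    raise ValueError(f"unknown defuzzification method {method!r}; choose from {_METHODS}")


def defuzzify(activations: tuple[float, float, float],
              rule_base: FuzzyRuleBase | None = None,
              method: str = "centroid",
              grid_resolution: int | None = None) -> DefuzzResult:
    """Clip, aggregate and defuzzify the rule ladder.

    Ordinal dominance is applied first: the high rule keeps its activation, the
    raised rule keeps only its excess over high, and low only its excess over
    raised, so the most severe applicable rule determines the crisp score.
    """
    rb = rule_base or default_rule_base()
    w_low, w_raised, w_high = activations
    for w in activations:
        if not 0.0 <= w <= 1.0:
            raise ValueError("activations must lie in [0, 1]")
    eff = (max(0.0, w_low - w_raised), max(0.0, w_raised - w_high), w_high)
    grid = rb.grid(grid_resolution)
    mu = np.zeros_like(grid)
    for w, fs in zip(eff, rb.output_sets()):
        if w > 0:
            mu = np.maximum(mu, np.minimum(w, fs.mu(grid)))
    if mu.sum() == 0.0:
        return DefuzzResult(None, "no-evidence", method, tuple(activations))
    crisp = _crisp(grid, mu, method)
    label = "poor" if crisp > rb.poor_threshold else "not-poor"
    return DefuzzResult(crisp, label, method, tuple(activations))


def defuzz_bnn(predictive, method: str = "centroid") -> float:
    """Defuzzify a posterior-predictive distribution over the outcome universe.

    The predictive mass is rescaled to peak 1 and treated as a membership
    function; the centroid of an exact point mass is its location.
    """
    grid = np.asarray(predictive.grid, float)
    mass = np.asarray(predictive.mass, float)
    if grid.size == 0 or mass.sum() <= 0:
        raise ValueError("degenerate predictive distribution")
    mu = mass / mass.max()
    integrate = "trapezoid" if grid.size >= 50 else "sum"
    return _crisp(grid, mu, method, integrate=integrate)


def classify_case(risk_factors: set[str] | list[str],
                  assignment: ClusterAssignment | None = None,
                  rule_base: FuzzyRuleBase | None = None,
                  method: str = "centroid",
                  antecedent: str = "presence") -> DefuzzResult:
    """End-to-end: risk-factor names -> memberships -> rules -> crisp prognosis.

    ``antecedent="presence"`` (default) saturates each cluster's membership to
    1 as soon as any member is present; ``"fraction"`` uses the graded
    fractional membership directly.
    """
    assignment = assignment or assign_clusters()
    m = memberships(set(risk_factors), assignment)
    if antecedent == "presence":
        m = MembershipDegrees(*(1.0 if v > 0 else 0.0 for v in m.as_tuple()))
    elif antecedent != "fraction":
        raise ValueError("antecedent must be 'presence' or 'fraction'")
    return defuzzify(rule_activations(m), rule_base, method=method)
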
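"""Canonical roster of the 30 aSAH predictor variables.

The roster, cluster labels (demographic / systemic / neurologic) and the two
published multivariable coefficient sets are fixture data shared by every
module.  Names follow the artificial-neural-network importance table; the
regression tables use slightly different labels and WinBUGS node names, which
the alias table maps onto the canonical roster.
"""

from __future__ import annotations

# name -> (kind, cluster)
_ROSTER: list[tuple[str, str, str]] = [
    ("Age", "continuous", "demographic"),
    ("Second stroke", "binary", "neurologic"),
    ("Myocardial infarction", "binary", "systemic"),
    ("Temperature", "continuous", "systemic"),
    ("Mean arterial pressure", "continuous", "systemic"),
    ("Neurological grade", "continuous", "neurologic"),
    ("Ruptured aneurysm size", "continuous", "neurologic"),
    ("Diabetes mellitus", "binary", "systemic"),
    ("Angina", "binary", "systemic"),
    ("SAH clot thickness", "continuous", "neurologic"),
    ("Lung edema", "binary", "systemic"),
    ("Admission angiographic vasospasm", "binary", "neurologic"),
    ("Previous subarachnoid hemorrhage", "binary", "neurologic"),
    ("Vasospasm day", "continuous", "neurologic"),
    ("Cerebral edema", "binary", "neurologic"),
    ("Vasospasm during treatment", "binary", "neurologic"),
    ("Aneurysm location", "binary", "neurologic"),
    ("Time to treatment", "continuous", "demographic"),
    ("Normal motor response", "binary", "neurologic"),
    ("Intracerebral hematoma", "binary", "neurologic"),
    ("Normal speech", "binary", "neurologic"),
    ("Day-8 temperature", "continuous", "systemic"),
    ("Gender", "binary", "demographic"),
    ("Eye opening", "binary", "neurologic"),
    ("Migraine history", "binary", "neurologic"),
    ("Intraventricular hemorrhage", "binary", "neurologic"),
    ("Hypertensive history", "binary", "systemic"),
    ("Anticoagulant use", "binary", "systemic"),
    ("Seizures", "binary", "neurologic"),
    ("Hydrocephalus", "binary", "neurologic"),
]

VARIABLE_NAMES: list[str] = [name for name, _, _ in _ROSTER]
KIND: dict[str, str] = {name: kind for name, kind, _ in _ROSTER}
CLUSTER: dict[str, str] = {name: cluster for name, _, cluster in _ROSTER}
CLUSTER_LABELS = ("demographic", "systemic", "neurologic")

# Documented synthetic marginals (not ground truth from any source; see the
# methods note).  Continuous: (mean, sd) in natural units.  Binary: prevalence.
CONTINUOUS_MARGINALS: dict[str, tuple[float, float]] = {
    "Age": (52.0, 12.0),                 # years
    "Temperature": (37.2, 0.7),          # deg C, admission
    "Mean arterial pressure": (105.0, 15.0),  # mmHg
    "Neurological grade": (2.5, 1.2),    # WFNS-like 1-5 scale, continuous proxy
    "Ruptured aneurysm size": (9.0, 5.0),     # mm
    "SAH clot thickness": (2.0, 1.0),    # Fisher-like blood-load proxy
    "Vasospasm day": (7.0, 3.0),         # days post-ictus
    "Time to treatment": (48.0, 24.0),   # hours
    "Day-8 temperature": (37.6, 0.8),    # deg C
}

BINARY_PREVALENCE: dict[str, float] = {
    "Second stroke": 0.25,
    "Myocardial infarction": 0.05,
    "Diabetes mellitus": 0.08,
    "Angina": 0.07,
    "Lung edema": 0.08,
    "Admission angiographic vasospasm": 0.20,
    "Previous subarachnoid hemorrhage": 0.10,
    "Cerebral edema": 0.30,
    "Vasospasm during treatment": 0.30,
    "Aneurysm location": 0.40,           # posterior-circulation indicator
    "Normal motor response": 0.80,
    "Intracerebral hematoma": 0.15,
    "Normal speech": 0.70,
    "Gender": 0.35,                      # male indicator
    "Eye opening": 0.75,
    "Migraine history": 0.10,
    "Intraventricular hemorrhage": 0.45,
    "Hypertensive history": 0.40,
    "Anticoagulant use": 0.05,
    "Seizures": 0.10,
    "Hydrocephalus": 0.20,
}

# Published frequentist multivariable coefficients (linear model on the
# reversed 5-point outcome; only significant predictors were reported, the
# rest default to 0).
TABLE1_BETAS: dict[str, float] = {
    "Normal motor response": -0.329,
    "Second stroke": 0.790,              # reported as "Cerebral infarction"
    "Myocardial infarction": 0.386,
    "Cerebral edema": 0.322,
    "Diabetes mellitus": 0.239,
    "Day-8 temperature": 0.231,          # reported as "Day-8 fever"
    "Previous subarachnoid hemorrhage": 0.197,
    "Admission angiographic vasospasm": 0.175,
    "Neurological grade": 0.167,
    "Intraventricular hemorrhage": 0.142,
    "Ruptured aneurysm size": 0.130,
    "Hypertensive history": 0.119,
    "Vasospasm day": 0.112,
    "Age": 0.018,
    "Mean arterial pressure": 0.003,
}

# Published Bayesian-regression posterior means (uninformed priors), keyed by
# canonical name; NODE_NAME gives the WinBUGS-style node label.
TABLE2_BETAS: dict[str, float] = {
    "Normal motor response": -0.3268,
    "Second stroke": 0.9499,
    "Cerebral edema": 0.4307,
    "Myocardial infarction": 0.2964,
    "Neurological grade": 0.2762,
    "Diabetes mellitus": 0.254,
    "Admission angiographic vasospasm": 0.2417,
    "Previous subarachnoid hemorrhage": 0.1747,
    "Ruptured aneurysm size": 0.2124,
    "Intraventricular hemorrhage": 0.1727,
    "Hypertensive history": 0.1223,
    "Vasospasm day": 0.05136,
    "Age": 0.01581,
    "Mean arterial pressure": 0.004209,
    "Day-8 temperature": -0.08723,
}

NODE_NAME: dict[str, str] = {
    "Normal motor response": "b.MOTOR",
    "Second stroke": "b.CVA",
    "Cerebral edema": "b.BSWELL",
    "Myocardial infarction": "b.MI",
    "Neurological grade": "b.NEUROGR",
    "Diabetes mellitus": "b.DM",
    "Admission angiographic vasospasm": "b.ADMITVSP",
    "Previous subarachnoid hemorrhage": "b.PREVSAH",
    "Ruptured aneurysm size": "b.ANSIZE",
    "Intraventricular hemorrhage": "b.IVH",
    "Hypertensive history": "b.HTN",
    "Vasospasm day": "b.VSPDAY",
    "Age": "b.AGE",
    "Mean arterial pressure": "b.MAP",
    "Day-8 temperature": "b.D8TEMP",
}


def _default_node(name: str) -> str:
    return "b." + "".join(ch for ch in name.upper() if ch.isalnum())[:10]


def node_name(name: str) -> str:
    """WinBUGS-style node label for a canonical variable name."""
    return NODE_NAME.get(name, _default_node(name))


# Aliases from regression-table labels, node names and clinical synonyms to
# canonical roster names.  Lookup is case-insensitive.
ALIASES: dict[str, str] = {
    "cerebral infarction": "Second stroke",
    "cva": "Second stroke",
    "history of myocardial infarction": "Myocardial infarction",
    "history of diabetes mellitus": "Diabetes mellitus",
    "history of hypertension": "Hypertensive history",
    "hypertension": "Hypertensive history",
    "hypertensive": "Hypertensive history",
    "diabetic": "Diabetes mellitus",
    "day-8 fever": "Day-8 temperature",
    "day 8 fever": "Day-8 temperature",
    "fever on day 8": "Day-8 temperature",
    "day 8 temperature": "Day-8 temperature",
    "prior subarachnoid hemorrhage": "Previous subarachnoid hemorrhage",
    "pulmonary edema": "Lung edema",
    "subarachnoid clot thickness": "SAH clot thickness",
    "sah thickness": "SAH clot thickness",
    "intracerebral hemorrhage": "Intracerebral hematoma",
    "elderly": "Age",
    "coronary artery disease": "Angina",
    "cerebral ischemia": "Vasospasm during treatment",
    "antiepileptic use": "Seizures",
    "history of angina": "Angina",
    "history of migraines": "Migraine history",
    "migraines": "Migraine history",
    "anticoagulation": "Anticoagulant use",
    "prior anticoagulation": "Anticoagulant use",
}
_CANONICAL_LOWER = {name.lower(): name for name in VARIABLE_NAMES}
_NODE_LOWER = {node_name(name).lower(): name for name in VARIABLE_NAMES}


def resolve_name(name: str) -> str:
    """Map a variable label (canonical, alias, or node name) to its canonical form.

    Raises KeyError for labels that cannot be resolved.
    """
    key = name.strip().lower()
    if key in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[key]
    if key in ALIASES:
        return ALIASES[key]
    if key in _NODE_LOWER:
        return _NODE_LOWER[key]
    raise KeyError(f"unknown predictor variable: {name!r}")
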
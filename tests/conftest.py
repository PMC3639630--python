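import numpy as np
import pytest

from fuzzybnn import cohort as cohort_mod
from fuzzybnn.cohort import Cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient cohort generated under the frequentist coefficient set."""
    spec = cohort_mod.default_spec("table1", n=400)
    return cohort_mod.generate(spec, seed=42)


@pytest.fixture(scope="session")
def large_cohort():
    """Full-size (n=3551) cohort under the frequentist coefficient set."""
    spec = cohort_mod.default_spec("table1", n=3551)
    return cohort_mod.generate(spec, seed=7)


def toy_cohort(X, y_latent, gos=None, names=None):
    """Assemble a Cohort around an arbitrary design matrix for unit tests."""
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if gos is None:
        gos = np.ones(n, dtype=int)
    if names is None:
        names = [f"x{j}" for j in range(p)]
    return Cohort(X=X, y_latent=np.asarray(y_latent, float),
                  gos=np.asarray(gos, int), column_names=names)
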
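"""Shared fixtures: small synthetic cohorts and one cached pipeline run."""

import numpy as np
import pandas as pd
import pytest

from recuq import GeneratorSpec, generate_cohort, run_pipeline
from recuq.experiments import narrow_spec


@pytest.fixture(scope="session")
def small_table():
    """Narrow planted-signal cohort (55 features, n=150) shared across tests."""
    return generate_cohort(narrow_spec(11, 150))


@pytest.fixture(scope="session")
def small_run(small_table):
    """One full five-fold pipeline pass on the small cohort."""
    return run_pipeline(small_table, 11, importance=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def two_feature_fixture():
    """n=40 cohort with 2 informative features and 3 noise features.

    Deterministic; used where a hand-countable confusion table is needed.
    """
    gen = np.random.default_rng(7)
    n = 40
    x = gen.standard_normal((n, 5))
    logit = 1.8 * x[:, 0] - 1.8 * x[:, 1]
    y = (gen.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    cols = [f"ct_pre__radiomic_{i:03d}" for i in range(5)]
    values = pd.DataFrame(x, columns=cols, index=[f"S{i}" for i in range(n)])
    labels = pd.Series(y, index=values.index)
    return values, labels
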
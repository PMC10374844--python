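import numpy as np
import pandas as pd
import pytest

import ovrisk
from ovrisk.cohort import CohortTable, FeatureSchema


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    """One full-size synthetic cohort at the published study conditions."""
    return ovrisk.generate_cohort(ovrisk.default_config(seed=123))


@pytest.fixture()
def tiny_schema() -> list[FeatureSchema]:
    return [
        FeatureSchema("age", "Age", "continuous", "years"),
        FeatureSchema("bmi", "BMI", "continuous", "kg/m2"),
        FeatureSchema("brca1", "BRCA 1", "binary"),
        FeatureSchema("n_preg", "Pregnancies", "count"),
    ]


def make_tiny_cohort(schema, rows, outcomes, ids=None):
    """Build a CohortTable from explicit feature rows (NaN = missing)."""
    ids = ids or [f"P{i+1}" for i in range(len(rows))]
    df = pd.DataFrame(rows, columns=[f.name for f in schema])
    df.insert(0, "patient_id", ids)
    df["outcome"] = outcomes
    df["subtype"] = "none"
    return CohortTable(df, schema)


@pytest.fixture()
def tiny_cohort(tiny_schema) -> CohortTable:
    rows = [
        [50.0, 24.0, 1, 2],
        [30.0, 20.0, 0, 0],
        [49.0, np.nan, 1, 1],
        [55.0, 27.5, 0, 3],
        [42.0, 23.1, 0, 0],
        [61.0, 30.2, 1, 2],
    ]
    return make_tiny_cohort(tiny_schema, rows, [1, 0, 0, 1, 0, 0])


@pytest.fixture(scope="session")
def separable_xy():
    """Linearly separable 2-class training data (1 informative feature)."""
    rng = np.random.default_rng(42)
    n = 30
    X = rng.normal(size=(n, 4))
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    X[y == 1, 0] += 6.0
    return X, y
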
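import numpy as np
import pandas as pd
import pytest

from riskaudit import ClassSummaries, unit_schema


@pytest.fixture(scope="session")
def schema_2d():
    return unit_schema(2)


@pytest.fixture(scope="session")
def mixed_schema():
    """Two continuous + one binary feature."""
    return unit_schema(2, 1)


@pytest.fixture(scope="session")
def one_dim_summaries():
    """Single continuous feature, well-separated interior class normals."""
    schema = unit_schema(1)
    return ClassSummaries(
        schema=schema,
        mean_pos=np.array([0.7]),
        mean_neg=np.array([0.3]),
        cov_pos=np.array([[0.01]]),
        cov_neg=np.array([[0.01]]),
        prevalence=0.5,
        n_pos=1000,
        n_neg=1000,
    )


@pytest.fixture
def small_table(schema_2d):
    rng = np.random.default_rng(42)
    X = rng.random((40, 2))
    y = np.array([0, 1] * 20)
    return pd.DataFrame(X, columns=list(schema_2d.names)), y
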
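import numpy as np
import pandas as pd
import pytest

from varactivity.synthetic import generate_feature_table, study_config


@pytest.fixture(scope="session")
def study_dataset():
    """Study-conditions benchmark table (150 variants × 68 scores, seed 1)."""
    return generate_feature_table(study_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_linear_data(rng):
    """Complete-case regression problem with known coefficients, no outliers."""
    n = 120
    X = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, 4)), columns=["a", "b", "c", "d"]
    )
    beta = np.array([30.0, -20.0, 10.0, 0.0])
    y = pd.Series(50.0 + X.to_numpy() @ beta + rng.normal(0, 2.0, n), index=X.index)
    return X, y, beta
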
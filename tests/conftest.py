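import numpy as np
import pandas as pd
import pytest

from hte_emulate import (
    default_config,
    default_schema,
    design_matrix,
    generate_cohort,
    randomized_config,
)
from hte_emulate.schema import Covariate, CovariateSchema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    """Randomized-assignment cohort, n=600, protective main effect."""
    cfg = randomized_config(n_total=600, seed=7, treatment_main_effect=-0.4)
    table, oracle = generate_cohort(cfg, schema)
    return table, oracle


@pytest.fixture(scope="session")
def small_design(schema, small_cohort):
    table, _ = small_cohort
    X = design_matrix(table, schema)
    y = table["y_uncontrolled"].to_numpy(dtype=float)
    return X, y


@pytest.fixture(scope="session")
def default_cohort(schema):
    cfg = default_config(n_total=3092, seed=11)
    table, oracle = generate_cohort(cfg, schema)
    return table, oracle


@pytest.fixture()
def tiny_schema():
    """Four-covariate schema for imputation tests."""
    return CovariateSchema(
        (
            Covariate("x", "continuous"),
            Covariate("x_dup", "continuous"),
            Covariate("b", "binary"),
            Covariate("col", "categorical", ("a", "b", "c")),
        )
    )


def make_correlated_table(n: int, seed: int) -> pd.DataFrame:
    """x_dup duplicates x exactly; b and col depend on x."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    b = (x + 0.3 * rng.normal(0, 1, n) > 0).astype(float)
    col = pd.Categorical.from_codes(
        np.clip(np.digitize(x, [-0.5, 0.5]), 0, 2), categories=["a", "b", "c"]
    )
    return pd.DataFrame({"x": x, "x_dup": x.copy(), "b": b, "col": col})
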
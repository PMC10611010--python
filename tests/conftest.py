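import numpy as np
import pandas as pd
import pytest

from pm25ascvd import (
    ExposureConfig,
    OutcomeConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort with a known BC effect, default (approximate) closure."""
    return generate_cohort(
        n=8_000,
        seed=20_301,
        outcome_config=OutcomeConfig(true_beta={"BC": 0.4}),
    )


@pytest.fixture(scope="session")
def closure_cohort():
    """Exact-closure cohort with constituent-level ground truth for ISM tests."""
    return generate_cohort(
        n=6_000,
        seed=90_210,
        exposure_config=ExposureConfig(closure_mode="exact_sum"),
        outcome_config=OutcomeConfig(true_beta={"BC": 0.4, "SO4": 0.1}),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose outcome is independent of every exposure."""
    return generate_cohort(n=5_000, seed=777, outcome_config=OutcomeConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_2x2(n_exposed_cases=30, n_exposed=100, n_unexposed_cases=10, n_unexposed=100):
    """Expanded individual-level data for a 2x2 exposure/outcome table."""
    x = np.r_[np.ones(n_exposed), np.zeros(n_unexposed)]
    y = np.r_[
        np.ones(n_exposed_cases),
        np.zeros(n_exposed - n_exposed_cases),
        np.ones(n_unexposed_cases),
        np.zeros(n_unexposed - n_unexposed_cases),
    ]
    X = pd.DataFrame({"const": 1.0, "exposure": x})
    return X, pd.Series(y)
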
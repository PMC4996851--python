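"""Shared fixtures: small hand-checkable datasets and simulated cohorts."""

import numpy as np
import pytest

from coxbench import (
    SurvivalOutcome,
    WeibullPHModel,
    default_scenario_spec,
    generate_cohort,
    make_true_coefficients,
)


@pytest.fixture(scope="session")
def four_obs():
    """Four observations, all events at times 1..4, one binary covariate.

    In time order the covariate is (1, 0, 0, 1); risk-set sizes at the four
    event times are 4, 3, 2, 1.
    """
    time = np.array([1.0, 2.0, 3.0, 4.0])
    status = np.array([1, 1, 1, 1])
    x = np.array([[1.0], [0.0], [0.0], [1.0]])
    return x, SurvivalOutcome(time, status)


def simulate_cox_dataset(n, p, beta, seed, censor_quantile=0.7, rate=0.5):
    """Exponential-baseline Cox data with uniform censoring (test helper)."""
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n, p))
    T = -np.log(rng.random(n)) / (rate * np.exp(V @ np.asarray(beta, float)))
    C = rng.uniform(0, np.quantile(T, censor_quantile), n)
    return V, SurvivalOutcome(np.minimum(T, C), (T <= C).astype(int))


@pytest.fixture(scope="session")
def cox_dataset_200x10():
    """Fixed 200 x 10 dataset with moderate effects, ~50% events."""
    beta = np.array([0.5, -0.5, 0.3, 0.0, 0.0, 0.2, 0.0, 0.0, -0.3, 0.1])
    return simulate_cox_dataset(200, 10, beta, seed=202)


@pytest.fixture(scope="session")
def scenario1_truth():
    """Scenario-1 cohort (n=1000) with a known Weibull PH truth model."""
    spec = default_scenario_spec(1)
    X = generate_cohort(spec, 1000, seed=42)
    beta = make_true_coefficients(spec, 0.2, seed=7)
    model = WeibullPHModel(1.1, 0.08, beta, spec.names)
    return spec, X, model
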
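import logging

import numpy as np
import pytest

from heckmice import Dataset, HeckmanSpec, ScenarioConfig, gen_heckman_scenario

logging.getLogger("heckmice").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def binary_spec():
    return HeckmanSpec(outcome_var="Y", outcome_covars=["X1", "X2"],
                       selection_covars=["X1", "X2", "X3"], outcome_kind="binary")


@pytest.fixture
def continuous_spec():
    return HeckmanSpec(outcome_var="Y", outcome_covars=["X1", "X2"],
                       selection_covars=["X1", "X2", "X3"],
                       outcome_kind="continuous")


def simulate(kind: str, rho: float, n: int, seed: int):
    """One study-condition replicate (selection-model missingness)."""
    cfg = ScenarioConfig(outcome_kind=kind, rho=rho, n=n)
    return gen_heckman_scenario(cfg, np.random.default_rng(seed))


@pytest.fixture
def binary_sim():
    return simulate("binary", rho=0.6, n=500, seed=11)


@pytest.fixture
def continuous_sim():
    return simulate("continuous", rho=0.6, n=500, seed=12)


@pytest.fixture
def tiny_dataset():
    """Six cases, one missing outcome cell, one missing covariate cell."""
    values = np.array([
        [1.0, 0.2, -0.5],
        [0.0, -1.0, 0.3],
        [np.nan, 0.5, 0.8],
        [1.0, 1.2, np.nan],
        [0.0, -0.3, -0.2],
        [1.0, 0.1, 0.9],
    ])
    mask = ~np.isnan(values)
    return Dataset(values, ["Y", "X1", "X2"],
                   {"Y": "binary", "X1": "continuous", "X2": "continuous"}, mask)
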
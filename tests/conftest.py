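import numpy as np
import pytest

from robustpk import (
    MCMCConfig,
    ModelSpec,
    ObservationBlock,
    PKDataset,
    PriorSpec,
    preset_example,
    simulate_dataset,
)
from dataclasses import replace


@pytest.fixture(scope="session")
def example1_data():
    """One seeded draw from the clean 10-subject design, with truth."""
    data, truth = simulate_dataset(replace(preset_example(1), seed=20250101))
    return data, truth


@pytest.fixture
def tiny_data():
    """Hand-built 2-subject dataset for exact-arithmetic checks."""
    return PKDataset([
        ObservationBlock("A", np.array([1.0, 2.0, 4.0]),
                         np.array([1.2, 1.5, 1.1]), dose=10.0),
        ObservationBlock("B", np.array([0.5, 3.0]),
                         np.array([0.9, 1.3]), dose=10.0),
    ])


@pytest.fixture
def fast_config():
    """Short but converging sampler settings for unit tests."""
    return MCMCConfig(n_iter=800, burn_in=500, summary_window=300, seed=7)


@pytest.fixture
def t_spec():
    return ModelSpec(error_family="t", nu=4.0)


@pytest.fixture
def normal_spec():
    return ModelSpec(error_family="normal")


@pytest.fixture
def priors():
    return PriorSpec()
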
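import numpy as np
import pytest

from weightdiffusion import DiffusionParams, ScemConfig, load_group_series

#: constants printed for the full 24-week fit
GROUP_PARAMS_S24 = DiffusionParams(alpha=0.016337, beta=1.7096, initial_weight=69.39)
#: constants printed for the 12-week validation fit
GROUP_PARAMS_S12 = DiffusionParams(alpha=0.0170757, beta=1.7029, initial_weight=69.39)


@pytest.fixture(scope="session")
def group_series():
    return load_group_series()


@pytest.fixture(scope="session")
def s24(group_series):
    return group_series.window(1, 24)


@pytest.fixture(scope="session")
def s12(group_series):
    return group_series.window(1, 12)


@pytest.fixture
def fast_cfg():
    """Small sampler configuration for unit tests of the pipeline plumbing."""
    return ScemConfig(population_size=30, n_complexes=3, max_shuffles=20, min_shuffles=5, seed=7)


@pytest.fixture(scope="session")
def full_cfg():
    """Default-strength sampler configuration used for the headline fits."""
    return ScemConfig(seed=1)
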
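import numpy as np
import pytest

from marapop.inference import IPMModel, PriorSpec, initial_params
from marapop.states import initial_state_means
from marapop.synthetic import (
    ScenarioConfig,
    default_parameters,
    generate_dataset,
    initial_total_from_ground,
    june_proportions_from_ground,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic bundle (4 years) shared across unit tests."""
    cfg = ScenarioConfig(
        T=48, aerial_months=(6, 18, 30, 42), initial_reserve_total=3000.0
    )
    return generate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    ds = small_dataset
    tab = ds.covariate_table()
    init_means = initial_state_means(
        june_proportions_from_ground(ds.ground),
        initial_total_from_ground(ds.ground),
    )
    return IPMModel(
        ds.ground, ds.aerial, tab, ds.truth.predation, PriorSpec(), init_means
    )


@pytest.fixture(scope="session")
def small_params(small_dataset, small_model):
    rng = np.random.default_rng(99)
    return initial_params(small_model, small_dataset.truth.coeffs, rng)


@pytest.fixture(scope="session")
def true_params():
    return default_parameters()
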
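import numpy as np
import pytest

from metsim.model import (
    DIET_HFDC,
    Model,
    default_parameters,
    reference_state,
)


@pytest.fixture(scope="session")
def model():
    """Reference model under the low-fat diet."""
    return Model()


@pytest.fixture(scope="session")
def hfdc_model():
    """Reference model under the high-fat/high-cholesterol diet."""
    return Model(diet=DIET_HFDC)


@pytest.fixture(scope="session")
def theta():
    return default_parameters()


@pytest.fixture(scope="session")
def steady(model, theta):
    return model.steady_state(theta)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_positive_state(rng, scale=1.0):
    """Random strictly positive pool vector around the reference."""
    base = reference_state().values.copy()
    base[base == 0] = 1.0  # give the sinks a positive value too
    return base * np.exp(rng.normal(0.0, scale, base.size))


def random_params(rng, scale=0.5):
    base = default_parameters().values
    return base * np.exp(rng.normal(0.0, scale, base.size))
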
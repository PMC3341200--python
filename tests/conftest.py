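import numpy as np
import pytest

from pias3net import (
    experiment_catalog,
    find_steady_state,
    make_default_parameters,
)


@pytest.fixture(scope="session")
def params():
    """Default core parameters (methods dialect)."""
    return make_default_parameters("methods")


@pytest.fixture(scope="session")
def resting_state(params):
    """Resting steady state at baseline inputs, shared across the session."""
    return find_steady_state(params)


@pytest.fixture(scope="session")
def catalog():
    return experiment_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120208)
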
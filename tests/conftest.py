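import numpy as np
import pytest

from targetmr import simulate
from targetmr.model import DrugTargetMR


@pytest.fixture(scope="session")
def default_world():
    """The calibrated default world: 20 studies x 10 000, fixed seed."""
    return simulate.default_config(seed=0)


@pytest.fixture(scope="session")
def default_model(default_world):
    return DrugTargetMR.from_simulation(default_world)


@pytest.fixture(scope="session")
def default_results(default_model):
    """Fitted results of the full calibrated run (shared across tests)."""
    return default_model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170201)
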
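import pytest

from minesafety.cause_weights import DEFAULT_TAXONOMY, default_weight_table
from minesafety.model24 import default_parameters
from minesafety.sd_engine import SimulationConfig


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def true_weights():
    return default_weight_table()


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()
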
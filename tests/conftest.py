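import numpy as np
import pytest

from absheet.model import build_topology, default_parameter_table


@pytest.fixture(scope="session")
def topo():
    return build_topology("KLVFFAE")


@pytest.fixture(scope="session")
def table():
    return default_parameter_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
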
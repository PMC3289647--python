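import numpy as np
import pytest

from erevar.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """One default-scale synthetic input set shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    paths, truth = simulate_all(SimConfig(seed=7), out)
    return paths, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
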
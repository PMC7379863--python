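import numpy as np
import pytest

from effortframe.benchmarks import _recovery_battery


@pytest.fixture(scope="session")
def recovery_battery():
    """30 quadratic agents (k log-uniform over two decades, beta=10) with
    their 40-trial staircase choice sets; shared across recovery tests."""
    return _recovery_battery(n_agents=30, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
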
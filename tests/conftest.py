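import numpy as np
import pytest

from elpcip import SimScenario, simulate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A compact but complete scenario shared by read-only tests."""
    return simulate_scenario(SimScenario(rng_seed=7, n_probesets=40))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
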
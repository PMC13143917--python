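import numpy as np
import pytest

from asdyn import engine


@pytest.fixture(scope="session")
def vignette_scenario():
    return engine.restaurant_vignette()


@pytest.fixture(scope="session")
def vignette_bundle(vignette_scenario):
    return engine.run_scenario(vignette_scenario, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
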
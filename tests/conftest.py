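import numpy as np
import pytest

from flashkin import biological_system, water_system


@pytest.fixture(scope="session")
def water_sys():
    return water_system()


@pytest.fixture(scope="session")
def bio_sys():
    return biological_system()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
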
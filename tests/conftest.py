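import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model_1x4():
    from spnsim.network import build_model

    return build_model(1, 4)


@pytest.fixture(scope="session")
def model_1x2():
    from spnsim.network import build_model

    return build_model(1, 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
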
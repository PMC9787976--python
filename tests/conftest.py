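import numpy as np
import pytest

from tracefear import design


@pytest.fixture(scope="session")
def acq_schedule():
    return design.generate_schedule("acquisition", seed=1)


@pytest.fixture(scope="session")
def recall_schedule():
    return design.generate_schedule("recall", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
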
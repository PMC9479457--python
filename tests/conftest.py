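import numpy as np
import pytest

import streamseg as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nh_profile():
    return ss.get_profile("NH")


@pytest.fixture(scope="session")
def ci2_profile():
    return ss.get_profile("CI2")
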
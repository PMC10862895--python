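import numpy as np
import pytest

from switchscope.synthetic import make_toy_topology


@pytest.fixture
def toy_topology():
    """Seven-residue toy topology spanning all three default switch regions."""
    return make_toy_topology([50, 52, 173, 201, 226, 228, 259])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
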
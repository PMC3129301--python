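import numpy as np
import pytest

from retroclock import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cfg():
    """Down-scaled simulation config for fast unit tests."""
    return SimConfig(ltr_len=300, internal_len=1000, domain_len=400, seed=0)
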
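import numpy as np
import pytest
from hypothesis import settings

from taudamage import SECTION31_TEXT

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def params():
    """Default published constant set."""
    return SECTION31_TEXT


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
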
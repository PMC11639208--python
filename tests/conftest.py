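import numpy as np
import pytest

from headcount import SyntheticFieldSpec, generate_field
from headcount.encoding import ToyExtractor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field():
    """One deterministic 64x64 field with 3 exemplar boxes."""
    return generate_field(SyntheticFieldSpec(seed=7))


@pytest.fixture(scope="session")
def toy_extractor():
    return ToyExtractor(channels=16, seed=0)
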
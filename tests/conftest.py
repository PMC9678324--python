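import numpy as np
import pytest

from helios import CodingParams


@pytest.fixture
def default_params() -> CodingParams:
    return CodingParams()  # R=4, k=5, optical code scales


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
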
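import numpy as np
import pytest

from gsrel import VarianceSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20160303)


@pytest.fixture
def vs04():
    return VarianceSpec(nu2=0.4)
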
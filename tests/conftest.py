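import numpy as np
import pytest

from dutchpt import OpponentBelief, ProspectParams


@pytest.fixture
def tk_params() -> ProspectParams:
    """Canonical utility/weighting values with neutral V and moderate c."""
    return ProspectParams(c=1.0, V=1.0)


@pytest.fixture
def belief() -> OpponentBelief:
    return OpponentBelief(mu=2.01, sigma=0.97, n_opponents=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
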
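import numpy as np
import pytest

from chemotrails import DynamicsParams, FieldParams


@pytest.fixture(scope="session")
def fp() -> FieldParams:
    """Default chemorepellent field (measured micelle diffusivity)."""
    return FieldParams()


@pytest.fixture(scope="session")
def dyn() -> DynamicsParams:
    """Default CAPP parameters (measured V0 and median couplings)."""
    return DynamicsParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def zero_field(r, t):
    return 0.0, np.zeros(np.asarray(r).shape[-1])
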
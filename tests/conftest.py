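import numpy as np
import pytest

from kintraffic.params import ModelParams, PausingParams


@pytest.fixture(scope="session")
def kinesin_params() -> ModelParams:
    """The literature-anchored kinesin-1 parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def pausing_params() -> PausingParams:
    return PausingParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
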
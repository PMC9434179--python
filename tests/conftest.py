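import numpy as np
import pytest

from compensim import SimulationParams


@pytest.fixture
def default_params() -> SimulationParams:
    """The standard study conditions: N=10,000, c=0.15, p=0.5, n=100."""
    return SimulationParams()


@pytest.fixture
def tiny_params() -> SimulationParams:
    """A toy instance small enough for exact enumeration."""
    return SimulationParams(
        N=10,
        G=20,
        mu=0.01,
        c=0.15,
        p=0.5,
        n=1,
        m=0,
        allow_second_mutation=False,
        presence_threshold=1,
        sample_size=5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
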
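import numpy as np
import pytest

from snarcpower import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    return SimulationParams(slope=-4.0, n=5, k=6, sdr=100.0)


def zero_errors(count):
    """Noise-free error hook: isolates the deterministic part of the model."""
    return np.zeros(count)
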
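import numpy as np
import pytest

from swallowmetrics.hydration import ThicknessSeries
from swallowmetrics.synthetic import GeneratorConfig


@pytest.fixture
def quiet_cfg() -> GeneratorConfig:
    """Noiseless deterministic generator configuration."""
    return GeneratorConfig(seed=0, noise_sd=0.0)


@pytest.fixture
def noisy_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=7, noise_sd=0.005)


@pytest.fixture
def simple_series() -> ThicknessSeries:
    """Three-point single-replicate series with hand-checkable values."""
    return ThicknessSeries("demo", [0.0, 4.0, 8.0], [[1000.0, 1100.0, 1250.0]])
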
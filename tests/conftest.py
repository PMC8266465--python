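import numpy as np
import pytest
from hypothesis import settings

from ginsquant.library import STANDARD_LIBRARY, zero_intercept_library
from ginsquant.synthetic import SyntheticRunConfig

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def printed_library():
    """The 25 standards with their reported calibration laws."""
    return STANDARD_LIBRARY


@pytest.fixture(scope="session")
def library():
    """The 25 standards under proportional (zero-intercept) response."""
    return zero_intercept_library()


@pytest.fixture
def clean_config():
    """Noise-free deterministic generator settings."""
    return SyntheticRunConfig(seed=7)


@pytest.fixture
def noisy_config():
    """Two-percent area dispersion plus baseline noise."""
    return SyntheticRunConfig(seed=7, area_cv=0.02, baseline_sd=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
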
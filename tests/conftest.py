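import numpy as np
import pytest

from rhinoflow import SyntheticSpec, default_thresholds, generate_effective_cycle


@pytest.fixture
def thresholds():
    return default_thresholds()


@pytest.fixture
def clean_cycle():
    """A noise-free effective cycle: f=0.3 Hz, pressure VPP 500 Pa, flow VPP 1000."""
    spec = SyntheticSpec(
        frequency_hz=0.3,
        pressure_amp_pa=250.0,
        flow_amp_cm3s=500.0,
        noise_sigma_frac=0.0,
        seed=0,
    )
    return generate_effective_cycle(spec).cycle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
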
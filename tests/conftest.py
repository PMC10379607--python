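import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from porescan import GeneratorConfig, make_native, make_state_templates


@pytest.fixture(scope="session")
def native():
    return make_native(40, seed=1)


@pytest.fixture(scope="session")
def states(native):
    return make_state_templates(native, displacement_per_state=0.5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_campaign_config():
    """A small, fast campaign: 12 replicas, 4 ns at 50 ps, quiet noise."""
    return GeneratorConfig(
        n_replicas=12,
        duration=4.0,
        frame_interval=50.0,
        n_atoms=30,
        noise_sigma=0.01,
        fraction_unstable=0.0,
        fraction_closed=0.0,
        unstable_ramp_window=2.0,
        seed=42,
    )
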
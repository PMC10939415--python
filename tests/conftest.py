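import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adaptce import DesignConfig, EndpointMarginals

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def dialysis_endpoints():
    """Peritoneal-dialysis worked example: peritonitis/membrane deterioration
    (relevant, p0=0.615, OR=0.52) and technical failure (p0=0.15, OR=0.66)."""
    return EndpointMarginals(0.615, 0.52), EndpointMarginals(0.15, 0.66)


@pytest.fixture
def cfg():
    """Default design: one-sided alpha 0.05, power 0.80, equal allocation."""
    return DesignConfig(alpha=0.05, beta=0.2, pi=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
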
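import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cd38pkpd as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def typical_pk() -> m.PKParams:
    return m.PKParams.monkey_typical()


@pytest.fixture(scope="session")
def linear_pk(typical_pk) -> m.PKParams:
    """Typical parameters with target binding switched off (KSYN=0)."""
    return typical_pk.replace(KSYN=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
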
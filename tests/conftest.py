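import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circatrend.preprocess import Design

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_design() -> Design:
    """The emulated experiment: samples every 2 h over 48 h, 3 replicates."""
    return Design.regular(np.arange(0.0, 49.0, 2.0), 3)
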
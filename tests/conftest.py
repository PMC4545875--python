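import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hubshift.montage import standard_montage
from hubshift.simulate import study_preset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage19():
    return standard_montage()


@pytest.fixture(scope="session")
def montage21():
    return standard_montage(include_unclustered=True)


@pytest.fixture(scope="session")
def preset():
    """The calibrated study preset (posterior lower-alpha coupling matched
    to the published control/severe PLI means); calibrated once per
    session."""
    return study_preset(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
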
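import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings(
    "ignore", message=".*all-constant feature.*", category=UserWarning
)


@pytest.fixture
def config():
    from bopdscreen.ehr import StudyConfig

    return StudyConfig()
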
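import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tcrrep import SegmentSet, toy_reference  # noqa: E402


@pytest.fixture(scope="session")
def toy_set() -> SegmentSet:
    return toy_reference()
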
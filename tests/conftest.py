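import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pednutriscreen import (  # noqa: E402
    bundled_registry,
    synthetic_reference_library,
)


@pytest.fixture(scope="session")
def references():
    return synthetic_reference_library()


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()
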
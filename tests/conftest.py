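import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from peachfls import SimulationConfig, generate_locus  # noqa: E402


@pytest.fixture(scope="session")
def published_fixture():
    """Locus fixture embedding the published junction fragments (seed 42)."""
    return generate_locus(SimulationConfig(seed=42), published_fragments=True)


@pytest.fixture(scope="session")
def small_fixture():
    """A compact random fixture for fast simulation-heavy tests."""
    return generate_locus(SimulationConfig(seed=7, locus_length=1500))
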
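import pytest
from hypothesis import HealthCheck, settings

from ncdratio import ScenarioConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Six countries (one per WHO region), both sexes, three years."""
    return ScenarioConfig(n_countries=6, years=(2007, 2012, 2017), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)
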
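import pytest
from hypothesis import HealthCheck, settings

from cdc_lossmap import SimConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def study_config() -> SimConfig:
    """The benchmark cohort: 200 somatic at VAF 0.3 / depth 100,
    200 germline, 100 artifacts, clean sequencing, seed 1."""
    return SimConfig(seed=1)


@pytest.fixture
def clean_config() -> SimConfig:
    """Noise-free variant of the cohort: exact downstream recovery holds."""
    return SimConfig(seed=1, fish_noise=0.0, logr_sd=0.0, sequencing_error_rate=0.0)
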
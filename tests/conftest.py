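import pytest
from hypothesis import HealthCheck, settings

from dosagegi import SimConfig
from dosagegi.synthetic import simulate_ground_truth

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A down-scaled screen: enough strains for statistics, fast to simulate."""
    return SimConfig(seed=123, n_kinases=12, n_tfs=40, wt_replicates=8,
                     n_sdl_queries=1, n_ddl_queries=1, gi_rate=0.1)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_ground_truth(small_config)
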
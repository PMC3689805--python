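import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnaimap import default_map, simulate_riail_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_map():
    """Two 40-cM chromosomes, 2-cM marker spacing (42 markers)."""
    return default_map(chromosomes=("I", "II"), length_cM=40.0, spacing_cM=2.0)


@pytest.fixture(scope="session")
def small_panel(small_map):
    return simulate_riail_panel(small_map, n_lines=120, g_intercross=6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
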
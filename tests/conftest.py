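import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctdnatrack.datasets import relapse_example
from ctdnatrack.synthetic_data import SimulationConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture()
def relapse_ex():
    return relapse_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=3, relapse_fraction=1 / 3, seed=42)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(small_config, out)
    return out
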
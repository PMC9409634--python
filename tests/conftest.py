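import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small but complete synthetic study on disk (session-scoped)."""
    from hrvpart.pipeline import simulate_study

    path = tmp_path_factory.mktemp("study")
    simulate_study(path, n_per_group=(8, 12, 8), seed=7)
    return path
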
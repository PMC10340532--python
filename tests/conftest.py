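import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pilot96():
    from mcakscreen.plates import builtin_layout

    return builtin_layout("pilot96")


@pytest.fixture
def pilot384():
    from mcakscreen.plates import builtin_layout

    return builtin_layout("pilot384")


@pytest.fixture
def default_config():
    from mcakscreen.plates import RunConfig

    return RunConfig()
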
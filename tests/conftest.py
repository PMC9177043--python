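import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathmetad import double_channel_protocol, rotor_flip_protocol, run_multipmd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return rotor_flip_protocol()


@pytest.fixture(scope="session")
def default_run(default_config):
    """The reference two-path run (inside + outside) at the default protocol."""
    return run_multipmd(default_config, seed=0)


@pytest.fixture(scope="session")
def channel_run():
    """Single-loop run on the generic 2D double-channel landscape."""
    return run_multipmd(double_channel_protocol(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
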
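import pytest
from hypothesis import settings

from gaitpipe.synthetic_gait import GaitSimConfig, simulate_gait

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_walk():
    """One noise-free walk under the default capture protocol."""
    return simulate_gait(GaitSimConfig())


@pytest.fixture(scope="session")
def small_walk():
    """A short two-pass walk (one turnaround), noise-free."""
    return simulate_gait(GaitSimConfig(n_passes=2))
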
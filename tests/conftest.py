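import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sdfusion.simlocus import SimConfig, simulate_locus  # noqa: E402


@pytest.fixture(scope="session")
def default_locus():
    """One default recurrent-scenario locus shared by read-only tests."""
    cfg = SimConfig(seed=11)
    aln, truth = simulate_locus(cfg)
    return cfg, aln, truth


@pytest.fixture(scope="session")
def ibd_locus():
    cfg = SimConfig(seed=11, scenario="ibd")
    aln, truth = simulate_locus(cfg)
    return cfg, aln, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
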
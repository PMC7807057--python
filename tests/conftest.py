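import numpy as np
import pytest
from hypothesis import settings

from hapdyad import ObserverParams, SimConfig, run_experiment

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_experiment():
    """One full simulated experiment with the design defaults (8 blocks,
    equal observers), shared across read-only tests."""
    cfg = SimConfig(seed=7)
    return cfg, *run_experiment(cfg)


@pytest.fixture(scope="session")
def unequal_experiment():
    """A larger cohort of disagreement trials from members with clearly
    different noise levels, for leadership-feature property checks."""
    cfg = SimConfig(
        n_blocks=25,
        observers=(ObserverParams(sigma=4.0), ObserverParams(sigma=9.0)),
        seed=11,
    )
    return cfg, *run_experiment(cfg)
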
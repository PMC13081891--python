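import numpy as np
import pytest

from pleiofm.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_signal_study():
    """One-region homogeneous study with a single strong causal gene."""
    cfg = SimulationConfig(
        scenario="homogeneous",
        n1=250,
        n2=1500,
        n_regions=1,
        q=12,
        m=2,
        h2=0.05,
        causal_per_region=(1, 1),
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_null_study():
    cfg = SimulationConfig(
        scenario="null",
        n1=200,
        n2=600,
        n_regions=1,
        q=9,
        m=2,
        h2=0.05,
        seed=7,
    )
    return simulate_study(cfg)
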
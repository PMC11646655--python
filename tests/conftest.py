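import numpy as np
import pytest

from pdpmvar import PanelTimeSeries, SimulationDesign, gen_setting


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small stable cluster-structured panel reused across tests."""
    return gen_setting(
        SimulationDesign(
            setting=1, n=12, D=4, T=80, K=2, sparsity=0.75,
            n_theta_clusters=2, n_sigma_clusters=2, seed=7,
        )
    )


@pytest.fixture
def tiny_panel(rng):
    X1 = rng.standard_normal((3, 30))
    X2 = rng.standard_normal((3, 25))
    return PanelTimeSeries([("a", X1), ("b", X2)], n_lags=2)
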
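import numpy as np
import pytest

import psforage as pf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A deliberately small world for fast unit tests."""
    return pf.WorldConfig(W=100, N=12, V_R=6, s_r=5, n_rounds=50, d_F=10)


@pytest.fixture(scope="session")
def trained_distant():
    """One ensemble trained on the distant-food task (standard settings)."""
    cfg = pf.WorldConfig(d_F=21)
    rng = np.random.default_rng(2021)
    return pf.train_ensemble(cfg, rng, n_trials=10_000)


@pytest.fixture(scope="session")
def trained_near():
    """One ensemble trained on the nearby-food task."""
    cfg = pf.WorldConfig(d_F=4)
    rng = np.random.default_rng(2004)
    return pf.train_ensemble(cfg, rng, n_trials=10_000)
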
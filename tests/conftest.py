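import numpy as np
import pytest

import plnnfc as pf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model():
    """Untrained but seeded network: d=10, widths [10, 4, 3, 1]."""
    cfg = pf.ModelConfig(layer_widths=[10, 4, 3, 1], seed=7)
    return pf.init_model(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted-edge cohort shared across tests (p=10, 30/group)."""
    spec = pf.CohortSpec(
        p=10, n_per_group=30, T=150, delta=0.5,
        planted_edges=[(0, 1), (2, 3), (4, 5), (6, 7)], seed=11,
    )
    return spec, pf.simulate_dataset(spec)


@pytest.fixture(scope="session")
def trained_tiny(tiny_cohort):
    """Network trained on the tiny cohort (fast, deterministic)."""
    _, ds = tiny_cohort
    cfg = pf.ModelConfig(
        layer_widths=[ds.d, 8, 4, 1], dropout_rate=0.1, epochs=60,
        learning_rate=2e-3, seed=5,
    )
    return pf.train(ds.X, ds.y, cfg)
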
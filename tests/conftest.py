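import numpy as np
import pytest

from personet import (make_ring_truth, make_temporal_truth, sample_covariates,
                      simulate_panel)
from personet.model_core import ModelParams, SymptomPanel


@pytest.fixture(scope="session")
def ring_truth():
    return make_ring_truth(10)


@pytest.fixture(scope="session")
def stable_truth():
    return make_temporal_truth(seed=20240901)


@pytest.fixture(scope="session")
def ring_panel(ring_truth):
    """A medium ring-truth panel (n=800, T=3), shared across tests."""
    return simulate_panel(ring_truth, np.empty((800, 0)), 3, seed=11)


@pytest.fixture(scope="session")
def stable_panel(stable_truth):
    """A covariate-moderated panel (n=600, T=3), shared across tests."""
    X = sample_covariates(600, d=5, seed=12)
    return simulate_panel(stable_truth, X, 3, seed=13)


@pytest.fixture
def tiny_panel():
    """Deterministic 6-subject, T=3, p=3, d=2 panel for exact-value tests."""
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, size=(6, 3, 3))
    X = np.column_stack([rng.integers(0, 2, 6).astype(float),
                         rng.normal(0, 1, 6)])
    return SymptomPanel(y, X, covariate_kinds=["binary", "numeric"])


@pytest.fixture
def small_params():
    """Small hand-set parameters (p=3, d=2)."""
    p, d = 3, 2
    params = ModelParams.zeros(p, d)
    params.mu[:] = [-2.0, 0.5, -1.0]
    params.alpha[0, 0] = 0.7
    params.alpha[2, 1] = -0.3
    params.sigma1[0, 1] = 1.0
    params.sigma1[1, 1] = -0.5
    params.sigma1[2, 0] = 2.0
    params.gamma1[0, 1, 0] = 2.0
    params.gamma1[2, 2, 1] = 0.8
    return params
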
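"""Shared fixtures: trained models (session-scoped, trained once) and a
common labeled fBm test ensemble.

Training configurations here are scaled for a desk-class single-CPU run;
they reach within a few thousandths of the converged validation MAE of the
full default configuration.
"""
import numpy as np
import pytest

from hurstnet import fbm, network


@pytest.fixture(scope="session")
def model_n100():
    """Triangular, 3 hidden layers, 100-point windows (headline model)."""
    spec = network.NetworkSpec("triangular", 100, 3)
    cfg = network.TrainingConfig(n_train=100_000, n_val=5_000, max_epochs=15, patience=3)
    return network.train(spec, cfg, seed=101)


@pytest.fixture(scope="session")
def model_n40_sub():
    """Triangular, 3 hidden layers, trained on 40-of-100 subsampled windows."""
    spec = network.NetworkSpec("triangular", 40, 3)
    cfg = network.TrainingConfig(
        n_train=120_000, n_val=5_000, max_epochs=25, patience=4, subsample_from=100
    )
    return network.train(spec, cfg, seed=102)


@pytest.fixture(scope="session")
def model_n15():
    """Triangular, 3 hidden layers, 15-point windows (segmentation model)."""
    spec = network.NetworkSpec("triangular", 15, 3)
    cfg = network.TrainingConfig(n_train=150_000, n_val=5_000, max_epochs=20, patience=4)
    return network.train(spec, cfg, seed=103)


@pytest.fixture(scope="session")
def model_n41():
    """Triangular, 3 hidden layers, 41-point windows (residence-time model)."""
    spec = network.NetworkSpec("triangular", 41, 3)
    cfg = network.TrainingConfig(n_train=150_000, n_val=5_000, max_epochs=25, patience=4)
    return network.train(spec, cfg, seed=104)


@pytest.fixture(scope="session")
def fbm_test_ensemble():
    """2000 fresh 100-point fBm tracks with H ~ U(0,1) (shared test set)."""
    rng = np.random.default_rng(99)
    h = rng.uniform(0.001, 0.999, size=2000)
    pos = fbm.simulate_fbm_ensemble(h, 100, rng=rng)
    return h, pos
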
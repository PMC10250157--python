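"""Shared fixtures: small synthetic datasets and tiny trained models."""

from __future__ import annotations

import numpy as np
import pytest

import spliceconv as sc
from spliceconv.training import TrainingConfig, train


@pytest.fixture(scope="session")
def small_acceptor_ds() -> sc.SpliceDataset:
    """Balanced strength-1 acceptor dataset, 400 windows."""
    cfg = sc.SyntheticConfig(site_type="acceptor", total=400, seed=101)
    return sc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_donor_ds() -> sc.SpliceDataset:
    cfg = sc.SyntheticConfig(site_type="donor", total=400, seed=202)
    return sc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_encoded(small_acceptor_ds):
    return small_acceptor_ds.encode(), small_acceptor_ds.labels()


def train_tiny(arch: str, x, y, seed: int = 0, epochs: int = 2):
    """Train an architecture briefly on a small split; returns (spec, weights, result)."""
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = n // 5
    va, tr = order[:n_val], order[n_val:]
    spec, init_w = sc.build_architecture(arch, input_len=x.shape[1], seed=seed)
    cfg = TrainingConfig(epochs=epochs, seed=seed, early_stop_patience=epochs)
    result = train(spec, init_w, (x[tr], y[tr]), (x[va], y[va]), cfg)
    return spec, result.weights, result


@pytest.fixture(scope="session")
def tiny_trained_model1(small_encoded):
    """MODEL1 trained briefly on the small acceptor dataset."""
    x, y = small_encoded
    spec, weights, result = train_tiny("MODEL1", x, y, seed=7, epochs=2)
    return spec, weights, result
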
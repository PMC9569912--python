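"""Shared desk-scale fixtures: a small synthetic dataset and train config."""

import numpy as np
import pytest

from mildta.data import random_split
from mildta.synthetic import SynthConfig, generate_dt_dataset
from mildta.training import TrainConfig

TINY_ARCH = {
    "d_model": 8,
    "n_layers": 1,
    "n_heads": 2,
    "ffn_dim": 16,
    "n_gate_blocks": 1,
    "dilation_rates": [1],
    "scorer_hidden": [8],
    "drug_max_len": 10,
    "protein_max_len": 16,
}


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = SynthConfig(
        n_drugs=12,
        n_targets=8,
        density=0.6,
        drug_len_range=(8, 16),
        target_len_range=(16, 30),
        noise_sd=0.0,
        seed=11,
    )
    ds, truth = generate_dt_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    ds, _ = tiny_dataset
    return random_split(ds, seed=0)


def tiny_train_config(**overrides) -> TrainConfig:
    base = dict(
        batch_size=16,
        max_epochs=4,
        patience=10,
        seed=0,
        drug_vocab_size=24,
        protein_vocab_size=40,
        arch=dict(TINY_ARCH),
    )
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture()
def tiny_config():
    return tiny_train_config()
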
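import numpy as np
import pytest

from stgsl import (ModelConfig, TissueSimConfig, TrainConfig,
                   generate_layered_tissue, train)


def small_model_config(**kw) -> ModelConfig:
    """A low-dimensional architecture for fast unit tests."""
    base = dict(h_p=32, F=32, h_o=16, d_o=8, h=16, d_emb=8, h_phi=8, d_z=4,
                k=10, k_gamma=5)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_layered_tissue(
        TissueSimConfig(n_cells=150, n_genes=30, n_layers=3,
                        markers_per_layer=3, seed=7))


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A briefly trained model on the tiny fixture (shared, read-only)."""
    cfg = TrainConfig(epochs=10, seed=3, model=small_model_config())
    model, log = train(tiny_dataset, cfg)
    return model, log, tiny_dataset
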
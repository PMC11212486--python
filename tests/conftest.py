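import numpy as np
import pytest

from cppmine.embedders import MockEmbedder
from cppmine.featurization import FeatureConfig
from cppmine.model import ModelConfig, TrainConfig


@pytest.fixture
def tiny_features() -> FeatureConfig:
    """Small feature extractor for fast unit tests."""
    return FeatureConfig(pad_len=20, d_model=32, n_heads=4, ffn_dim=64,
                         branch_dim=32, conv_channels=8, residue_dim=48)


@pytest.fixture
def tiny_model_cfg(tiny_features) -> ModelConfig:
    return ModelConfig(features=tiny_features, mlp_hidden=(16, 8))


@pytest.fixture
def tiny_train_cfg() -> TrainConfig:
    return TrainConfig(batch_positives=8, epochs=3, seed=0)


@pytest.fixture
def mock_embedder(tiny_features) -> MockEmbedder:
    return MockEmbedder(residue_dim=tiny_features.residue_dim, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
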
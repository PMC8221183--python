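import numpy as np
import pytest

from sognn.features import normalize_per_subject, pad_features
from sognn.model import SOGNNConfig
from sognn.synth import SyntheticSpec, generate_features
from sognn.training import TrainConfig, run_loso

TINY_PAD = 40  # frame target matching SOGNNConfig.tiny_preset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Desk-scale synthetic dataset: 6 subjects x 12 trials, 16 electrodes."""
    ds = generate_features(SyntheticSpec.tiny(seed=1))
    padded = [pad_features(s, TINY_PAD) for s in ds.samples]
    return ds, padded


@pytest.fixture(scope="session")
def study_train_config():
    """Desk-scale training settings used for all synthetic study runs."""
    return TrainConfig(learning_rate=1e-3, max_epochs=15, seed=1)


@pytest.fixture(scope="session")
def tiny_loso(tiny_dataset, study_train_config):
    """One full LOSO run on the tiny dataset, with branch adjacencies."""
    ds, padded = tiny_dataset
    report, adjacencies = run_loso(
        padded, SOGNNConfig.tiny_preset(), study_train_config, collect_adjacency=True
    )
    return report, adjacencies


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def normalized_tiny(tiny_dataset):
    _, padded = tiny_dataset
    return normalize_per_subject(padded)
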
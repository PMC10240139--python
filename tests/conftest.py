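import numpy as np
import pytest

from retseg.network import NetworkConfig, build_network
from retseg.synthetic import SyntheticConfig, generate_arrays
from retseg.trainer import ArrayDataset


@pytest.fixture(scope="session")
def tiny_net_config() -> NetworkConfig:
    return NetworkConfig(depth=3, base_channels=4)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small 32-px synthetic pool shared across training tests."""
    cfg = SyntheticConfig(image_size=32, n_labeled=10, n_unlabeled=12, seed=5)
    imgs, masks, unl = generate_arrays(cfg)
    train = ArrayDataset(imgs[:8], {k: v[:8] for k, v in masks.items()})
    val = ArrayDataset(imgs[8:], {k: v[8:] for k, v in masks.items()})
    unlabeled = ArrayDataset(unl)
    return train, val, unlabeled


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
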
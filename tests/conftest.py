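import numpy as np
import pytest

from oxyflick import datasets
from oxyflick.rbc import RBCTrainConfig, generate_train


@pytest.fixture(scope="session")
def white_100k():
    """Long white-noise trace used by several calibration tests."""
    return datasets.make_white_noise(10 ** 5, 30.0, seed=1)


@pytest.fixture(scope="session")
def fgn_h09():
    """Long fractional Gaussian noise with H = 0.9."""
    return datasets.make_fgn(2 ** 17, 30.0, 0.9, seed=2)


@pytest.fixture(scope="session")
def train_beta1():
    """A 20-minute correlated RBC train with target exponent 1.0."""
    cfg = RBCTrainConfig(target_beta=1.0, duration=1200.0)
    return generate_train(cfg, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
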
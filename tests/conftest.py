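import numpy as np
import pytest

from vecspeckle.dataset import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40-sample static dense-medium dataset shared by training/CLI tests."""
    cfg = SimConfig(grid=32, medium="dense", coupling=0.5, ballistic_fraction=0.3)
    return generate_dataset(cfg, 40, seed=11)


@pytest.fixture(scope="session")
def epoch_dataset():
    """4 drift epochs of 25 samples each."""
    cfg = SimConfig(grid=32, medium="dense", n_epochs=4, drift_rate=0.3)
    return generate_dataset(cfg, 100, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
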
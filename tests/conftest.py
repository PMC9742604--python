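import numpy as np
import pytest

from atatnet import (ModelConfig, PhantomSpec, TrainConfig, block_covariance,
                     simulate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TINY_GRID = (8, 8, 8)
TINY_N = 4
TINY_Q = 16


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(
        grid_shape=TINY_GRID, n_rois=TINY_N, n_timepoints=TINY_Q, roi_radius=1,
        class_covariances={0: block_covariance(TINY_N, [[0, 1]], 0.8),
                           1: block_covariance(TINY_N, [[0, 1]], 0.0)},
        noise_sd=0.3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec, {0: 3, 1: 3}, seed=7)


@pytest.fixture
def tiny_model_config():
    return ModelConfig(grid_shape=TINY_GRID, n_rois=TINY_N, n_timepoints=TINY_Q,
                       n_blocks=2, channels=(4, 8), n_heads=4, seed=3)


@pytest.fixture
def tiny_train_config():
    return TrainConfig(epochs=1, batch_size=2, seed=3)
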
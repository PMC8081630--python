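"""Shared fixtures: one trained scoring model and standard phantom pairs.

Training the siamese network is the expensive step, so a single model
(2000 synthetic pairs, fixed seeds) is trained once per session and shared
by every test that needs a trained scorer.
"""

import numpy as np
import pytest

from sistfuse.cnn_model import CNNConfig, build_model, make_training_pairs, train_model
from sistfuse.phantoms import PhantomSpec, make_complementary_blur_pair

TRAIN_N_PAIRS = 2000
TRAIN_DATA_SEED = 7
TRAIN_SEED = 3
MODEL_SEED = 1
EPOCHS = 10


@pytest.fixture(scope="session")
def training_pairs():
    return make_training_pairs(TRAIN_N_PAIRS, seed=TRAIN_DATA_SEED)


@pytest.fixture(scope="session")
def trained_model(training_pairs):
    model = build_model(CNNConfig(seed=MODEL_SEED))
    return train_model(model, training_pairs, epochs=EPOCHS, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def blur_phantom():
    """256x256 complementary-blur pair with ground truth (A sharp on the left)."""
    return make_complementary_blur_pair(PhantomSpec(size=(256, 256), seed=11))


@pytest.fixture(scope="session")
def small_blur_phantom():
    """128x128 variant for cheaper end-to-end checks."""
    return make_complementary_blur_pair(PhantomSpec(size=(128, 128), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
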
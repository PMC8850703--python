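import logging

import numpy as np
import pytest

import ecgsubband as e

# Sub-band entropy drops are expected and logged in a few edge-case tests;
# keep the test output readable.
logging.getLogger("ecgsubband").setLevel(logging.ERROR)

FIXTURE_SEED = 0  # master seed of the frozen synthetic study fixture


@pytest.fixture(scope="session")
def default_dataset():
    """The frozen 150-record synthetic dataset (50 per class, 2 s at 250 Hz)."""
    return e.generate_dataset(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """54-column feature matrix of the frozen dataset."""
    fm = e.build_feature_matrix(default_dataset)
    assert fm.n_rows == 150
    return fm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
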
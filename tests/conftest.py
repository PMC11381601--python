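import numpy as np
import pytest

from glucospec.classifier import SpectrogramClassifier
from glucospec.datasets import make_classification_dataset


@pytest.fixture(scope="session")
def tiny_images():
    """Small 32x32 three-class image set with a trace-level 80/20 split."""
    return make_classification_dataset(n_segments_per_class=36, image_size=32, seed=7)


@pytest.fixture(scope="session")
def tiny_classifier(tiny_images):
    """A small trained classifier shared by downstream-module tests."""
    x_tr, y_tr, _, _ = tiny_images
    clf = SpectrogramClassifier(
        image_size=32,
        n_filters=8,
        lstm_hidden=8,
        fc_nodes=16,
        n_epochs=4,
        batch_size=16,
        learning_rate=3e-3,
        seed=0,
    )
    return clf.fit(x_tr, y_tr)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
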
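import numpy as np
import pytest

from fracband.model import BranchConfig, DecompositionConfig, FractureClassifier, TrainConfig
from fracband.synthetic import SyntheticSpec, generate_arrays


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small strongly-separable synthetic dataset shared across tests."""
    spec = SyntheticSpec(n_fracture=20, n_nonfracture=20, seed=7)
    images, labels = generate_arrays(spec)
    order = np.random.default_rng(1).permutation(len(labels))
    return images[order], labels[order]


def make_classifier(seed=0, subbands=("LL", "LH", "HL", "HH"), max_epochs=6, **train_kw):
    return FractureClassifier.create(
        branch_config=BranchConfig(backbone_id="tiny"),
        train_config=TrainConfig(seed=seed, subbands=subbands,
                                 max_epochs=max_epochs, **train_kw),
        decomposition=DecompositionConfig(method="dwt2", wavelet="haar"),
        seed=seed,
    )


@pytest.fixture(scope="session")
def trained_model(tiny_dataset):
    """A quickly trained model on the tiny dataset (tiny backbone)."""
    images, labels = tiny_dataset
    model = make_classifier(seed=0, max_epochs=4, early_stop_patience=3)
    model.fit(images[:30], labels[:30], images[30:], labels[30:])
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
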
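import numpy as np
import pytest

from tmhkit import TrainConfig, generate_cohort, train_segmenter


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def cohort300():
    """The scaled-down screening cohort: 300 phantoms, 30 % dry-eye prevalence."""
    return generate_cohort(300, dry_eye_fraction=0.3, seed=5)


@pytest.fixture(scope="session")
def training_run():
    """One full training of the convolutional segmenter, shared across tests.

    200 train / 50 val phantoms at 128x128, 30 epochs, fixed seed; returns
    (model, log, train_samples, val_samples).
    """
    cohort = generate_cohort(250, seed=11)
    train, val = cohort[:200], cohort[200:]
    model, log = train_segmenter(train, val, TrainConfig(max_epochs=30, seed=0))
    return model, log, train, val
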
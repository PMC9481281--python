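import numpy as np
import pytest

from anobeat.preprocess import normalize_matrix
from anobeat.synthetic import SimConfig, make_dataset
from anobeat.training import TrainConfig, train


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, jitter-free simulation settings."""
    return SimConfig(noise_sd=0.0, baseline_amp=0.0, amplitude_jitter=0.0,
                     width_jitter=0.0, seed=11)


@pytest.fixture(scope="session")
def small_trained():
    """A quickly trained model plus held-out scored beats, shared across
    detection/scoring tests.  Small but real: 160 normal training beats,
    40 + 40 test beats, a few adversarial epochs."""
    train_m, test_m = make_dataset(160, 40, 40, SimConfig(seed=5))
    train_n = normalize_matrix(train_m)
    test_n = normalize_matrix(test_m)
    model, history = train(
        train_n,
        config=TrainConfig(epochs=4, batch_size=32, seed=5),
    )
    return {
        "model": model,
        "history": history,
        "train": train_n,
        "test": test_n,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
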
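import numpy as np
import pytest

from somnoscore.simulate import GeneratorConfig, simulate_dataset
from somnoscore.staging import SleepStager


@pytest.fixture(scope="session")
def small_dataset():
    """Six simulated recordings of 200 epochs (feature-level, default mix)."""
    config = GeneratorConfig(n_psgs=6, n_epochs=200, seed=11)
    features, stages = simulate_dataset(config)
    return config, features, stages


@pytest.fixture(scope="session")
def small_stager(small_dataset):
    """A compact staging model trained on five of the six small recordings."""
    _, features, stages = small_dataset
    return SleepStager(n_estimators=30, random_state=5).fit(
        features[:5], stages[:5])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
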
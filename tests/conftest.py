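import numpy as np
import pytest

from respreset import synthio


@pytest.fixture(scope="session")
def small_config() -> synthio.SynthConfig:
    return synthio.SynthConfig(n_anticipatory=12, n_nonanticipatory=12, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> synthio.SyntheticDataset:
    """One modest synthetic recording shared by read-only tests."""
    return synthio.generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
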
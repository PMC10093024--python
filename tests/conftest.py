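import numpy as np
import pytest

from pmikit import GeneratorConfig, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """~390 noise-free cases from the default grids; enough for sanity fits."""
    return generate_dataset(GeneratorConfig(count=400, seed=7))


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_dataset(small_dataset, 0.25, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
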
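import numpy as np
import pytest

from parapop.synth import SynthConfig, generate_paralogue_dataset, dataset_site_tables


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic paralogue dataset at the packaged default configuration."""
    return generate_paralogue_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_site_tables(default_dataset):
    return dataset_site_tables(default_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
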
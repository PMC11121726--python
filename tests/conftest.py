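import numpy as np
import pytest

import readacross as ra


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic dataset at the generator's defaults (136 compounds)."""
    return ra.generate_dataset(ra.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def trained_bundle(default_dataset):
    compounds, descriptors, _ = default_dataset
    return ra.train_readacross(compounds, descriptors)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
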
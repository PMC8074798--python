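import numpy as np
import pytest

from harvestledger.synthetic_data import (SyntheticConfig, generate_tree,
                                          noiseless)


@pytest.fixture(scope="session")
def noiseless_config():
    return noiseless()


@pytest.fixture(scope="session")
def noiseless_tree(noiseless_config):
    """A deterministic noise-free synthetic tree with exact ground truth."""
    return generate_tree(noiseless_config, seed=42, index=0)


@pytest.fixture(scope="session")
def noisy_tree():
    """A synthetic tree under the default (noisy) study conditions."""
    return generate_tree(SyntheticConfig(), seed=42, index=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)
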
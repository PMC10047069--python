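import numpy as np
import pytest

from subspaceuq.datasets import SyntheticConfig, generate_embeddings
from subspaceuq.head import HeadParameters


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale cohort: 16-d embeddings, a handful of patients per class."""
    return SyntheticConfig(
        dim=16,
        n_train_pos=6,
        n_train_neg=8,
        n_test_pos=5,
        n_test_neg=6,
        n_neg_subclusters=4,
        augment_target_per_class=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_embeddings(small_config)


@pytest.fixture()
def identity_head() -> HeadParameters:
    """2-d head with pass-through normalization and zero dense layer."""
    return HeadParameters.zeros(2)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
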
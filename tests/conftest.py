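import numpy as np
import pytest

from microsel import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40 samples x 200 genes with 20 planted informative genes."""
    cfg = SyntheticConfig(n_healthy=17, n_malignant=23, n_genes=200,
                          n_informative=20, effect_size=1.5,
                          noise_family="gaussian", seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
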
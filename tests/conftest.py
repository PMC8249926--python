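import numpy as np
import pytest

from wchc import model_config, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """N=200, M=4 dataset with moderate signal on the second factor."""
    spec = model_config(2, M=4, beta=0.2, N=200)
    return simulate_dataset(spec, seed=7)


@pytest.fixture
def null_dataset():
    """N=500, M=8 dataset with no genetic effect."""
    spec = model_config(2, M=8, beta=0.0, N=500)
    return simulate_dataset(spec, seed=11)


def random_polymorphic_genotype(rng, n, maf=0.3):
    g = rng.binomial(2, maf, size=n)
    if g.min() == g.max():  # force polymorphism for tiny n
        g[0], g[1] = 0, 1
    return g
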
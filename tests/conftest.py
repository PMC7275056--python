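import numpy as np
import pytest

from mtar.sumstats import default_variants


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_genotypes(rng):
    """50 x 3 random 0/1/2 genotype matrix with polymorphic columns."""
    while True:
        g = rng.integers(0, 3, size=(50, 3)).astype(float)
        if np.all(g.std(axis=0) > 0):
            return g


def make_variants(m, start=100, spacing=50):
    return default_variants(m, start=start, spacing=spacing)


@pytest.fixture
def variants3():
    return make_variants(3)
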
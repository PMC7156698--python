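import numpy as np
import pytest

from minepi import make_space


@pytest.fixture
def square():
    """The two-locus bi-allelic space: four genotypes, one face."""
    return make_space(2, 2)


@pytest.fixture
def cube():
    """Three bi-allelic loci: the 3-cube with six faces."""
    return make_space(3, 2)


@pytest.fixture
def space33():
    """Three sites, three alleles: small but non-binary."""
    return make_space(3, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_additive(space, rng):
    """A random landscape with no epistasis: constant plus per-site effects."""
    basis = space.interaction_basis([0, 1])
    return basis @ rng.standard_normal(basis.shape[1])
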
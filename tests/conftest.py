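import numpy as np
import pytest

from deepscope import GenomeLayout, build_trait, generate_founders


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """7 chromosomes x 20 loci, 20 QTLs, deterministic placement."""
    return GenomeLayout.default(
        n_loci=140, n_chromosomes=7, n_qtl=20, rng=np.random.default_rng(7)
    )


@pytest.fixture
def small_trait(small_layout):
    return build_trait(small_layout.n_qtl, rng=np.random.default_rng(8))


@pytest.fixture
def default_layout():
    return GenomeLayout.default(rng=np.random.default_rng(1))


@pytest.fixture
def small_pools(small_layout):
    return generate_founders(
        small_layout, n_per_pool=(30, 30), rng=np.random.default_rng(42)
    )
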
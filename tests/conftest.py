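import numpy as np
import pytest

from moveflora.pools import Community, SpeciesPool, build_synthetic_pool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pool():
    """Deterministic 20-species pool spanning the trait axis."""
    return build_synthetic_pool(20, abundance_shape=1.0, seed=42)


@pytest.fixture
def three_species_community():
    """Hand-sized community: traits 0.2/0.5/0.8, counts 5/3/2."""
    return Community(
        ids=np.array(["a", "b", "c"], dtype=object),
        traits=np.array([0.2, 0.5, 0.8]),
        counts=np.array([5, 3, 2]),
    )


@pytest.fixture
def mono_community():
    return Community(
        ids=np.array(["only"], dtype=object),
        traits=np.array([0.3]),
        counts=np.array([50]),
    )


def make_pool(ids, traits, abundance):
    return SpeciesPool(
        ids=np.array(ids, dtype=object),
        traits=np.array(traits, dtype=float),
        rel_abundance=np.array(abundance, dtype=float),
    )
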
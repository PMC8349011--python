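import numpy as np
import pytest

from xrcompare.synthetic_data import WorldConfig, build_world


@pytest.fixture(scope="session")
def small_world():
    """Compact world for structural tests (fast to build, genomes cheap)."""
    cfg = WorldConfig(
        genome_length=1_000_000,
        n_chroms=2,
        n_genes=100,
        n_homolog_regions=60,
        region_length=(500, 2_000),
        seed=11,
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def default_world():
    """The default-parameter world (500 regions, 50 planted duplications)."""
    return build_world(WorldConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
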
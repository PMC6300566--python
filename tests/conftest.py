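import pytest

from netenrich.io_formats import DiseaseCatalog, InteractionNetwork, PathwayCollection
from netenrich.synthetic_data import SyntheticConfig, generate_study


@pytest.fixture
def chain_network():
    """A - B (0.8), B - C (0.8): the canonical 3-node extraction fixture."""
    return InteractionNetwork.from_edges([("A", "B", 0.8), ("B", "C", 0.8)])


@pytest.fixture
def small_pathways():
    pc = PathwayCollection()
    pc.add("P1", "first", ["A", "B"])
    pc.add("P2", "second", ["B", "C", "D"])
    return pc


@pytest.fixture
def small_catalog(small_pathways):
    cat = DiseaseCatalog()
    cat.add("D1", "nervous", "P1")
    cat.add("D1", "nervous", "P2")
    cat.add("D2", "metabolic", "P2")
    return cat


@pytest.fixture(scope="session")
def tiny_config():
    """Small unplanted study: fast enough for per-test regeneration."""
    return SyntheticConfig(
        n_genes=400,
        mean_degree=8,
        n_pathways=12,
        pathway_size_range=(10, 30),
        n_diseases=6,
        pathways_per_disease_range=(1, 2),
        n_seeds=4,
        planted_fraction=0.0,
        n_truth_pairs=0,
        n_truth_diseases=0,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate_study(tiny_config)
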
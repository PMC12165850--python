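import pytest

from ippoint.anchor_index import build_index
from ippoint.chain_io import extract_anchor_blocks
from ippoint.core import ProjectionParams
from ippoint.simulate import standard_fixture


def make_indexes(sim, species_subset=None, min_block_size=10):
    """AnchorIndex per species pair of a simulation, optionally restricted."""
    species_subset = set(species_subset) if species_subset else set(sim.species)
    indexes = {}
    for pair, chains in sim.all_chains().items():
        if pair[0] in species_subset and pair[1] in species_subset:
            anchors = []
            for chain in chains:
                anchors.extend(extract_anchor_blocks(chain, min_block_size))
            indexes[pair] = build_index(anchors)
    return indexes


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced simulation for unit tests (fast; same generative model)."""
    sim, queries, truth = standard_fixture(seed=7, n_anchors=60, n_queries=80)
    return sim, queries, truth


@pytest.fixture(scope="session")
def standard_sim():
    """The standard study condition: 4 species, 200 anchors, 500 queries."""
    return standard_fixture(seed=42, n_anchors=200, n_queries=500)


@pytest.fixture(scope="session")
def default_params():
    return ProjectionParams()
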
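import pytest

from palmkaryo import simulate as sim
from palmkaryo import synteny as syn


@pytest.fixture(scope="session")
def standard_sim():
    """The default study conditions: 6-chromosome ancestor, two WGD rounds
    per lineage with fusions/fissions/inversions and 0.8 retention."""
    return sim.standard_simulation()


@pytest.fixture(scope="session")
def standard_blocks(standard_sim):
    """Cross-genome synteny blocks chained from truth homology."""
    anchors = syn.build_anchors(standard_sim.genome_a, standard_sim.genome_b,
                                standard_sim.truth.cross_pairs())
    return syn.chain_anchors(anchors, genome_a="A", genome_b="B")
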
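import numpy as np
import pytest

from oriscan.ancestral import Phylogeny
from oriscan.blocks import AlignedBlock, BlockRow, GeneSegment
from oriscan.pipeline import substitution_analysis
from oriscan.replicon import Replicon, Topology, assign_terminus
from oriscan.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def toy_circular_replicon() -> Replicon:
    """The 100-bp circular worked example: origin at 20, terminus at 60."""
    return Replicon(name="toy", length=100, origin=20, terminus=60)


@pytest.fixture(scope="session")
def three_taxon_fixture():
    """Three-taxon worked example: ((a,b),c); a,b carry the focal column with
    base C at genomic position 3, c carries A at position 9."""
    tree = Phylogeny.from_newick("((a:1.0,b:1.0):1.0,c:2.0);")
    block = AlignedBlock(
        id="toy3",
        rows=[
            BlockRow("a", "TGC", 1, "+"),
            BlockRow("b", "TGC", 1, "+"),
            BlockRow("c", "TGA", 7, "+"),
        ],
    )
    segment = GeneSegment(
        id="toy3.seg1",
        seqs={r.taxon: r.seq for r in block.rows},
        position_maps=dict(block.position_maps),
        strands={r.taxon: "+" for r in block.rows},
        codon_pos=np.array([1, 2, 3], dtype=np.int8),
    )
    return tree, block, segment


@pytest.fixture(scope="session")
def small_sim():
    """A 40-kb, 4-taxon simulation with rearrangements, shared across tests."""
    cfg = SimulationConfig(
        seed=5, n_taxa=4, length=40_000, block_span=(3_000, 8_000), rearrangement_rate=0.5
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    return substitution_analysis(
        small_sim.blocks, small_sim.annotations, small_sim.tree, small_sim.replicon
    )
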
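"""Chain homolog pairs into synteny blocks and read off the 4:4 signal.

Anchors (homologous gene pairs in rank space) are chained into collinear
blocks per chromosome pair; counting how many distinct blocks cover each
window of gene ranks gives the syntenic copy number of every region. Two
WGD rounds in each lineage predict a modal multiplicity of 4 in both
genomes -- the dotplot ratio that identifies shared ancestral chromosomes.
"""

from palmkaryo import simulate as sim
from palmkaryo import synteny as syn

std = sim.standard_simulation(seed=1)
anchors = syn.build_anchors(std.genome_a, std.genome_b,
                            std.truth.cross_pairs())
blocks = syn.chain_anchors(anchors, max_gap=25, min_block_anchors=5,
                           genome_a="A", genome_b="B")

print(f"{len(anchors)} anchors chained into {len(blocks)} blocks")
plus = sum(b.orientation == "+" for b in blocks)
print(f"orientations: {plus} forward, {len(blocks) - plus} inverted")
print(f"median anchors per block: "
      f"{sorted(b.score for b in blocks)[len(blocks) // 2]}")

prof = syn.block_multiplicity(blocks, window=20)
print(f"modal syntenic multiplicity: {prof.modal['A']}:{prof.modal['B']} "
      "(expected 4:4 after two WGDs per lineage)")
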
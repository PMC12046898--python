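"""Reconstruct the ancestral karyotype and the chromosome-event history.

Connected components of the block-segment graph recover the ancestral
chromosomes ("colors"); painting the extant genome with them exposes
fusion junctions, from which fusion/fission counts are estimated and
checked against the chromosome-count algebra
6 -> WGD -> 12 -> (+2, -5) -> 9 -> WGD -> 18 -> (+1, -3) -> 16.
"""

from palmkaryo import karyotype as kt
from palmkaryo import simulate as sim
from palmkaryo import synteny as syn
from palmkaryo.karyotype import Epoch, KaryotypeScenario

std = sim.standard_simulation(seed=1)
anchors = syn.build_anchors(std.genome_a, std.genome_b,
                            std.truth.cross_pairs())
blocks = syn.chain_anchors(anchors, genome_a="A", genome_b="B")

groups = kt.infer_ancestral_groups(blocks, min_component_genes=30)
print(f"{len(groups)} ancestral chromosome groups "
      f"(sizes: {[g.total_genes for g in groups]})")

painting = kt.paint_chromosomes(std.genome_a, groups)
print(f"painting covers {painting.coverage:.1%} of lineage-A genes over "
      f"{painting.n_chromosomes} chromosomes")

scen = kt.infer_event_scenario(painting, n_wgd=2, n_ancestral=len(groups))
print(f"inferred events: {scen.total_fusions} fusions, "
      f"{scen.total_fissions} fissions across two WGD epochs")

check = kt.event_accounting(len(groups), scen)
print(f"accounting check: n0={check.n0} -> n_final={check.n_final} "
      f"(observed {painting.n_chromosomes})")

reference = kt.event_accounting(6, KaryotypeScenario(6, [
    Epoch(wgd=True, fissions=2, fusions=5),
    Epoch(wgd=True, fissions=1, fusions=3)]))
print("reference history:",
      " -> ".join(f"{step}: n={n}" for step, n in reference.steps))
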
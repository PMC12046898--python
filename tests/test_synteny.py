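"""Synteny: anchor construction, collinear chaining (with a brute-force
set-packing oracle), block multiplicity and allelic pairs."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from palmkaryo import simulate as sim
from palmkaryo import synteny as syn


def toy_anchors(points):
    return [syn.Anchor(f"a{i}", f"b{i}", "c1", "c2", ra, rb)
            for i, (ra, rb) in enumerate(points)]


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate every valid chain, then exact max-weight
# packing of disjoint chains (maximum total anchors covered)
# ---------------------------------------------------------------------------

def _enumerate_chains(pts, max_gap, min_block):
    n = len(pts)
    chains = set()

    def step_ok(i, j, sgn):
        da = pts[j][0] - pts[i][0]
        db = sgn * (pts[j][1] - pts[i][1])
        return 0 < da <= max_gap and 0 < db <= max_gap

    def extend(seq, sgn):
        if len(seq) >= min_block:
            chains.add(sum(1 << k for k in seq))
        for j in range(n):
            if j not in seq and step_ok(seq[-1], j, sgn):
                extend(seq + [j], sgn)

    for sgn in (1, -1):
        for i in range(n):
            extend([i], sgn)
    return list(chains)


def brute_force_optimum(pts, max_gap, min_block):
    chains = _enumerate_chains(pts, max_gap, min_block)
    size = {c: bin(c).count("1") for c in chains}
    contains = [[c for c in chains if c >> i & 1] for i in range(len(pts))]

    @lru_cache(maxsize=None)
    def solve(mask):
        if not mask:
            return 0
        i = (mask & -mask).bit_length() - 1
        best = solve(mask & (mask - 1))
        for c in contains[i]:
            if c & mask == c:
                best = max(best, size[c] + solve(mask & ~c))
        return best

    return solve((1 << len(pts)) - 1)


class TestBuildAnchors:
    def test_empty_homology_gives_no_anchors(self):
        g = sim.make_ancestor(1, 5, 0)
        out = syn.build_anchors(g, g, pd.DataFrame(columns=["gene_a",
                                                            "gene_b"]))
        assert out == []

    def test_identity_homology_gives_diagonal(self):
        g = sim.make_ancestor(2, 6, 0)
        hom = pd.DataFrame({"gene_a": [x.gene_id for x in g.genes()],
                            "gene_b": [x.gene_id for x in g.genes()]})
        anchors = syn.build_anchors(g, g, hom)
        assert all(a.rank_a == a.rank_b and a.chrom_a == a.chrom_b
                   for a in anchors)

    def test_unknown_gene_id_is_named(self):
        g = sim.make_ancestor(1, 3, 0)
        hom = pd.DataFrame({"gene_a": ["nope"], "gene_b": ["g1_0001"]})
        with pytest.raises(KeyError, match="nope"):
            syn.build_anchors(g, g, hom)

    def test_one_wgd_caps_anchor_fan_out(self):
        anc = sim.make_ancestor(2, 20, 1)
        ga, gb, truth = sim.evolve_lineages(
            anc, sim.EvolutionScenario(seed=1),
            sim.EvolutionScenario([sim.WGD()], seed=2))
        anchors = syn.build_anchors(ga, gb, truth.cross_pairs())
        fan = pd.Series([a.gene_a for a in anchors]).value_counts()
        assert fan.max() <= 2


class TestChainAnchors:
    def test_diagonal_plus_block(self):
        blocks = syn.chain_anchors(toy_anchors([(i, i) for i in range(5)]),
                                   max_gap=25, min_block_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "+" and blocks[0].score == 5

    def test_antidiagonal_minus_block(self):
        blocks = syn.chain_anchors(toy_anchors([(i, 4 - i) for i in range(5)]),
                                   max_gap=25, min_block_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "-" and blocks[0].score == 5

    def test_gap_constraint_breaks_chains(self):
        pts = [(0, 0), (1, 1), (2, 2), (30, 30), (31, 31), (32, 32)]
        blocks = syn.chain_anchors(toy_anchors(pts), max_gap=5,
                                   min_block_anchors=3)
        assert [b.score for b in blocks] == [3, 3]

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            syn.chain_anchors([], max_gap=0)
        with pytest.raises(ValueError):
            syn.chain_anchors([], min_block_anchors=1)

    def test_no_anchor_in_two_blocks_and_monotonicity(self, standard_blocks):
        seen = set()
        for b in standard_blocks:
            for a in b.anchors:
                assert (a.gene_a, a.gene_b) not in seen
                seen.add((a.gene_a, a.gene_b))
            ra = [a.rank_a for a in b.anchors]
            rb = [a.rank_b for a in b.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            assert rb == sorted(rb, reverse=b.orientation == "-")
            assert len(set(rb)) == len(rb)
            assert b.score >= 5

    def test_matches_brute_force_on_uniform_random_instances(self):
        """1000 uniform-random instances of 4-12 anchors on a 10x10 rank
        grid: greedy chaining attains the exact set-packing optimum."""
        rng = np.random.default_rng(20250502)
        for _ in range(1000):
            k = int(rng.integers(4, 13))
            pts = sorted({(int(rng.integers(0, 10)), int(rng.integers(0, 10)))
                          for _ in range(k)})
            greedy = sum(b.score for b in
                         syn.chain_anchors(toy_anchors(pts), 25, 5))
            assert greedy == brute_force_optimum(tuple(pts), 25, 5)

    def test_never_exceeds_optimum_on_contended_instances(self):
        """With two crossing planted runs greedy may fragment the second
        chain, but its total score never exceeds the exact optimum."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            pts = set()
            for _ in range(int(rng.integers(1, 3))):
                sgn = 1 if rng.random() < 0.5 else -1
                a, b = int(rng.integers(0, 6)), int(rng.integers(0, 12))
                for _ in range(int(rng.integers(5, 8))):
                    pts.add((a, b))
                    a += int(rng.integers(1, 3))
                    b += sgn * int(rng.integers(1, 3))
            pts = sorted(pts)[:12]
            greedy = sum(b.score for b in
                         syn.chain_anchors(toy_anchors(pts), 25, 5))
            assert greedy <= brute_force_optimum(tuple(pts), 25, 5)


class TestBlockPurity:
    def test_blocks_reject_decoy_homology(self, standard_sim):
        """With 10% random decoy pairs added to the homolog table, >=95% of
        anchors inside blocks are truth homologs."""
        truth = standard_sim.truth
        pairs = truth.cross_pairs()
        rng = np.random.default_rng(0)
        ga = [x.gene_id for x in standard_sim.genome_a.genes()]
        gb = [x.gene_id for x in standard_sim.genome_b.genes()]
        n_decoy = len(pairs) // 10
        decoys = pd.DataFrame({"gene_a": rng.choice(ga, n_decoy),
                               "gene_b": rng.choice(gb, n_decoy)})
        anchors = syn.build_anchors(standard_sim.genome_a,
                                    standard_sim.genome_b,
                                    pd.concat([pairs, decoys]))
        blocks = syn.chain_anchors(anchors, genome_a="A", genome_b="B")
        inblock = [(a.gene_a, a.gene_b) for b in blocks for a in b.anchors]
        good = sum(truth.is_homolog(x, y) for x, y in inblock)
        assert good / len(inblock) >= 0.95


class TestMultiplicity:
    def test_self_comparison_is_one_to_one(self):
        g = sim.make_ancestor(2, 60, 1)
        hom = pd.DataFrame({"gene_a": [x.gene_id for x in g.genes()],
                            "gene_b": [x.gene_id for x in g.genes()]})
        blocks = syn.chain_anchors(syn.build_anchors(g, g, hom),
                                   genome_a="S", genome_b="S")
        prof = syn.block_multiplicity(blocks, window=20)
        assert prof.modal == {"S": 1}

    def test_two_wgd_lineages_show_four_to_four(self, standard_blocks):
        prof = syn.block_multiplicity(standard_blocks, window=20)
        assert prof.modal == {"A": 4, "B": 4}

    @staticmethod
    def _after_extra_loss(standard_sim, retention):
        ga = sim.apply_event(standard_sim.genome_a, sim.Loss(retention),
                             rng=11)
        gb = sim.apply_event(standard_sim.genome_b, sim.Loss(retention),
                             rng=12)
        truth = sim.TruthHomology(
            "A", "B", {x.gene_id: x.ancestral_id for x in ga.genes()},
            {x.gene_id: x.ancestral_id for x in gb.genes()})
        blocks = syn.chain_anchors(
            syn.build_anchors(ga, gb, truth.cross_pairs()),
            genome_a="A", genome_b="B")
        return syn.block_multiplicity(blocks, window=20)

    def test_fractionation_monotonically_erodes_multiplicity(self,
                                                             standard_sim):
        """Extra fractionation never raises the modal syntenic copy number,
        and heavy fractionation (retention 0.1) drops it below 4."""
        mild = self._after_extra_loss(standard_sim, 0.4)
        heavy = self._after_extra_loss(standard_sim, 0.1)
        for g in ("A", "B"):
            assert mild.modal[g] <= 4
            assert heavy.modal[g] <= mild.modal[g]
            assert heavy.modal[g] < 4


class TestAllelicPairs:
    @pytest.fixture(scope="class")
    def haplotypes(self):
        anc = sim.make_ancestor(2, 80, 4)
        g = sim.evolve(anc, sim.EvolutionScenario([sim.WGD(),
                                                   sim.Loss(0.9)], seed=4))
        h1, h2, pairs = sim.clone_as_haplotypes(g, seed=4)
        blocks = syn.chain_anchors(
            syn.build_anchors(h1, h2, pairs.rename(
                columns={"gene_h1": "gene_a", "gene_h2": "gene_b"})),
            genome_a="H1", genome_b="H2")
        return h1, h2, blocks

    def test_identical_haplotypes_one_identical_pair_per_gene(self, haplotypes):
        h1, h2, blocks = haplotypes
        cds = sim.make_cds([h1, h2], seed=5)
        pairs = syn.find_allelic_pairs(blocks, cds, cds)
        assert len(pairs) == h1.n_genes
        assert all(p.identity_class == "identical" and p.cds_identity == 100.0
                   for p in pairs)
        assert len({p.gene_h1 for p in pairs}) == len(pairs)

    def test_planted_edit_fraction_recovered(self, haplotypes):
        """~26% of the second haplotype's CDS get small edits; the fraction
        of non-identical allelic pairs matches."""
        h1, h2, blocks = haplotypes
        cds = sim.make_cds([h1, h2], seed=6)
        edited = sim.mutate_cds_fraction(
            cds, [x.gene_id for x in h2.genes()], 0.26, seed=7)
        pairs = syn.find_allelic_pairs(blocks, cds, cds)
        frac = sum(p.identity_class != "identical" for p in pairs) / len(pairs)
        assert frac == pytest.approx(0.26, abs=0.02)
        flagged = {p.gene_h2 for p in pairs if p.identity_class != "identical"}
        assert flagged <= edited

    def test_single_substitution_identity(self):
        assert syn.cds_identity("ACGTACGTAC", "ACGAACGTAC") == 90.0

    def test_missing_cds_is_named(self, haplotypes):
        h1, h2, blocks = haplotypes
        cds = sim.make_cds([h1, h2], seed=5)
        bad = dict(cds)
        victim = blocks[0].anchors[0].gene_a
        del bad[victim]
        with pytest.raises(KeyError, match=victim):
            syn.find_allelic_pairs(blocks, bad, cds)
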
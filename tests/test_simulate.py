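"""Simulator: event algebra, truth bookkeeping, sequence and omics
generators."""

import json

import numpy as np
import pytest

from palmkaryo import io as pio
from palmkaryo import simulate as sim
from palmkaryo._codons import STOP_CODONS, count_sites


def _chrom_count_prediction(n0, events):
    n = n0
    for ev in events:
        if isinstance(ev, sim.WGD):
            n *= 2
        elif isinstance(ev, sim.Fusion):
            n -= 1
        elif isinstance(ev, sim.Fission):
            n += 1
    return n


class TestGenomeEvents:
    def test_ancestor_shape_and_determinism(self):
        g = sim.make_ancestor(6, 200, 1)
        assert g.n_chromosomes == 6 and g.n_genes == 1200
        g.validate()
        assert [x.gene_id for x in g.genes()] == \
            [x.gene_id for x in sim.make_ancestor(6, 200, 1).genes()]
        tiny = sim.make_ancestor(1, 1, 0)
        assert tiny.n_chromosomes == 1 and tiny.n_genes == 1
        with pytest.raises(ValueError):
            sim.make_ancestor(0, 5, 1)

    def test_wgd_doubles_fusion_decrements(self):
        g = sim.make_ancestor(6, 20, 1)
        g12 = sim.apply_event(g, sim.WGD())
        assert g12.n_chromosomes == 12
        g11 = sim.apply_event(g12, sim.Fusion(0, 1))
        assert g11.n_chromosomes == 11
        g11.validate()

    def test_loss_full_retention_is_identity(self):
        g = sim.make_ancestor(3, 30, 2)
        g2 = sim.apply_event(g, sim.Loss(retention=1.0), rng=0)
        assert [x.gene_id for x in g2.genes()] == [x.gene_id for x in g.genes()]

    def test_inversion_reverses_order_and_strands(self):
        g = sim.make_ancestor(1, 10, 3)
        g2 = sim.apply_event(g, sim.Inversion(0, 2, 7))
        ids = [x.gene_id for x in g.chromosomes[0][1]]
        ids2 = [x.gene_id for x in g2.chromosomes[0][1]]
        assert ids2 == ids[:2] + ids[2:7][::-1] + ids[7:]
        flipped = dict((x.gene_id, x.strand) for x in g2.genes())
        orig = dict((x.gene_id, x.strand) for x in g.genes())
        assert all(flipped[i] != orig[i] for i in ids[2:7])
        assert all(flipped[i] == orig[i] for i in ids[:2] + ids[7:])

    @pytest.mark.parametrize("seed", range(12))
    def test_chromosome_count_algebra_random_scenarios(self, seed):
        """n_final = ((n doubled at WGD) + #fissions - #fusions), in order,
        on random scenarios; ancestral ids survive everything but LOSS."""
        rng = np.random.default_rng(seed)
        g = sim.make_ancestor(4, 25, seed)
        anc_ids = {x.ancestral_id for x in g.genes()}
        events = []
        for _ in range(rng.integers(3, 9)):
            kind = rng.integers(0, 4)
            if kind == 0 and g.n_chromosomes < 40:
                events.append(sim.WGD())
            elif kind == 1 and g.n_chromosomes >= 2:
                events.append(sim.Fusion())
            elif kind == 2:
                events.append(sim.Fission())
            else:
                events.append(sim.Inversion())
            g = sim.apply_event(g, events[-1], rng=int(rng.integers(2**31)))
        assert g.n_chromosomes == _chrom_count_prediction(4, events)
        assert {x.ancestral_id for x in g.genes()} == anc_ids
        g.validate()

    def test_loss_never_orphans_an_ancestral_id(self):
        g = sim.make_ancestor(2, 40, 5)
        g = sim.apply_event(g, sim.WGD())
        anc = {x.ancestral_id for x in g.genes()}
        lost = sim.apply_event(g, sim.Loss(retention=0.05), rng=7)
        assert {x.ancestral_id for x in lost.genes()} == anc

    def test_betel_palm_scenario_reaches_sixteen_chromosomes(self):
        anc = sim.make_ancestor(6, 50, 1)
        g = sim.evolve(anc, sim.betel_palm_scenario(seed=9))
        assert g.n_chromosomes == 16

    def test_evolve_lineages_empty_scenarios_identity_pairing(self):
        anc = sim.make_ancestor(2, 10, 1)
        ga, gb, truth = sim.evolve_lineages(
            anc, sim.EvolutionScenario(), sim.EvolutionScenario())
        pairs = truth.cross_pairs()
        assert len(pairs) == anc.n_genes
        assert (pairs["gene_a"].str.removeprefix("A_")
                == pairs["gene_b"].str.removeprefix("B_")).all()

    def test_two_wgds_cap_copy_number_at_four(self):
        anc = sim.make_ancestor(2, 30, 1)
        two = sim.EvolutionScenario([sim.WGD(), sim.Loss(0.8), sim.WGD(),
                                     sim.Loss(0.8)], seed=3)
        _, _, truth = sim.evolve_lineages(anc, two, two)
        for genome in ("A", "B"):
            assert max(truth.copy_counts(genome).values()) <= 4


class TestSequenceSimulators:
    def test_codon_pair_zero_ks_identical(self):
        a, b, truth = sim.simulate_codon_pair(
            sim.SeqSimParams(length=50, ks_target=0.0, seed=1))
        assert a == b and truth == 0.0

    def test_codon_pair_stop_free(self):
        a, b, _ = sim.simulate_codon_pair(
            sim.SeqSimParams(length=500, ks_target=0.5, seed=2))
        for seq in (a, b):
            assert not any(seq[i:i + 3] in STOP_CODONS
                           for i in range(0, len(seq), 3))

    def test_codon_pair_truth_matches_target_over_seeds(self):
        """Mutation-log truth at ks_target 0.3 is unbiased: over 50 seeds
        the mean realized truth sits within 3 SE of 0.3."""
        truths = [sim.simulate_codon_pair(
            sim.SeqSimParams(length=2000, ks_target=0.3, seed=s))[2]
            for s in range(50)]
        se = np.std(truths, ddof=1) / np.sqrt(len(truths))
        assert abs(np.mean(truths) - 0.3) < 3 * se + 1e-12

    def test_ltr_zero_age_identical(self):
        p = sim.simulate_ltr_element(0.0, 5.6e-10, 1000, seed=1)
        assert p.ltr5 == p.ltr3 and p.d_truth == 0.0

    def test_ltr_truth_near_expectation(self):
        p = sim.simulate_ltr_element(2.5e6, 5.6e-10, 200_000, seed=3)
        # expected D = 2 mu T = 0.0028; Poisson noise ~ 4%
        assert abs(p.d_truth - 0.0028) / 0.0028 < 0.15

    def test_ltr_divergence_linear_in_age(self):
        d1 = np.mean([sim.simulate_ltr_element(1e6, 5.6e-10, 100_000, s).d_truth
                      for s in range(10)])
        d2 = np.mean([sim.simulate_ltr_element(2e6, 5.6e-10, 100_000, s + 50).d_truth
                      for s in range(10)])
        assert d2 / d1 == pytest.approx(2.0, rel=0.15)


class TestOmicsSimulators:
    def test_no_effect_means_no_planted_ase(self):
        ex = sim.simulate_expression(sim.ExprSimParams(n_pairs=20, effect=1.0,
                                                       seed=1))
        assert ex.truth_ase == set()

    def test_planted_fold_change_recovered_from_matrix(self):
        from palmkaryo.hap_ase import compute_tpm
        ex = sim.simulate_expression(sim.ExprSimParams(
            n_pairs=100, ase_fraction=0.1, effect=4.0, noise_sd=0.05, seed=2))
        tpm = compute_tpm(ex.counts, ex.lengths)
        ratios = []
        for g1, g2 in sorted(ex.truth_ase):
            s1 = ex.samples[ex.samples.haplotype == "H1"]["sample"]
            s2 = ex.samples[ex.samples.haplotype == "H2"]["sample"]
            m1, m2 = tpm.loc[g1, s1].mean(), tpm.loc[g2, s2].mean()
            ratios.append(max(m1, m2) / min(m1, m2))
        assert np.median(ratios) == pytest.approx(4.0, rel=0.25)

    def test_expression_bit_reproducible(self):
        p = sim.ExprSimParams(n_pairs=30, seed=7)
        a, b = sim.simulate_expression(p), sim.simulate_expression(p)
        assert a.counts.equals(b.counts) and a.lengths.equals(b.lengths)

    def _panel(self, seed, n_genes=2, n_samples=9):
        import pandas as pd
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(2.0 ** rng.normal(5, 1, (n_genes, n_samples)),
                            index=[f"gene{j}" for j in range(n_genes)],
                            columns=[f"s{i}" for i in range(n_samples)])
        tissues = pd.Series((["root", "stem", "leaf"] * 3)[:n_samples],
                            index=expr.columns)
        return expr, tissues

    def test_metabolome_planted_correlations(self):
        """Planted links at target_r 0.9 show empirical |r| > 0.8 for >=90%
        of links at n = 9 samples."""
        expr, tissues = self._panel(0)
        met = sim.simulate_metabolome(expr, tissues, sim.MetSimParams(
            n_metabolites=100, linked_fraction=0.2, target_r=0.9, seed=1))
        ok = 0
        X = np.log2(expr.to_numpy() + 1)
        M = np.log2(met.intensities.to_numpy() + 1)
        for _, row in met.truth_links.iterrows():
            mi = met.intensities.index.get_loc(row.metabolite)
            gi = expr.index.get_loc(row.gene)
            r = np.corrcoef(M[mi], X[gi])[0, 1]
            ok += abs(r) > 0.8
        assert ok / len(met.truth_links) >= 0.9

    def test_metabolome_null_has_no_strong_correlations(self):
        """With linked_fraction 0, >=95% of metabolites show |r| <= 0.8
        with every panel gene at n = 9."""
        expr, tissues = self._panel(1)
        met = sim.simulate_metabolome(expr, tissues, sim.MetSimParams(
            n_metabolites=200, linked_fraction=0.0, seed=2))
        X = np.log2(expr.to_numpy() + 1)
        M = np.log2(met.intensities.to_numpy() + 1)
        R = np.corrcoef(np.vstack([M, X]))[:len(M), len(M):]
        frac_clean = (np.abs(R) <= 0.8).all(axis=1).mean()
        assert frac_clean >= 0.95


class TestFixtures:
    def test_write_read_roundtrip(self, tmp_path):
        anc = sim.make_ancestor(2, 15, 1)
        ga, gb, truth = sim.evolve_lineages(
            anc, sim.EvolutionScenario([sim.WGD()], seed=1),
            sim.EvolutionScenario(seed=2))
        cds = sim.make_cds([ga, gb], seed=3)
        files = sim.write_fixtures(tmp_path, genome_a=ga, genome_b=gb,
                                   truth=truth, cds=cds)
        assert (tmp_path / "genes_A.gff3").exists()
        back = pio.read_gff3(tmp_path / "genes_A.gff3").set_index("gene_id")
        orig = ga.gene_table().set_index("gene_id")
        assert set(back.index) == set(orig.index)
        for col in ("chrom", "start", "end", "strand", "rank"):
            assert back[col].to_dict() == orig[col].to_dict()
        assert pio.read_fasta(tmp_path / "cds_A.fasta") == {
            x.gene_id: cds[x.gene_id] for x in ga.genes()}
        assert len(files) >= 5

    def test_gff3_is_one_based_inclusive(self, tmp_path):
        g = sim.make_ancestor(1, 1, 0)
        gene = next(g.genes())
        pio.write_gff3(g.gene_table(), tmp_path / "x.gff3")
        line = [ln for ln in (tmp_path / "x.gff3").read_text().splitlines()
                if not ln.startswith("#")][0].split("\t")
        assert int(line[3]) == gene.start + 1 and int(line[4]) == gene.end

    def test_truth_json_structure(self, tmp_path):
        anc = sim.make_ancestor(2, 10, 1)
        ga, gb, truth = sim.evolve_lineages(
            anc, sim.EvolutionScenario(seed=1), sim.EvolutionScenario(seed=2))
        sc = {"A": sim.scenario_to_dict(sim.EvolutionScenario(seed=1))}
        sim.write_fixtures(tmp_path, genome_a=ga, genome_b=gb, truth=truth,
                           scenarios=sc)
        data = json.loads((tmp_path / "truth.json").read_text())
        assert set(data) >= {"scenarios", "copy_counts", "gene_ancestry"}
        assert data["copy_counts"]["A"] == dict(truth.copy_counts("A"))
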
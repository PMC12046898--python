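"""Ground-truth genome and multi-omics simulator.

Everything downstream of this module (synteny chaining, ancestral-karyotype
inference, Ks/LTR dating, allele-specific expression, metabolite networks)
is exercised on data produced here, where the answer is known by
construction:

* an ancestral genome of ordered genes is evolved through whole-genome
  duplications (WGD), chromosome fusions/fissions, inversions and
  fractionation (per-copy gene loss), carrying stable ancestral-gene labels
  that define truth homology;
* codon-sequence pairs are diverged to a target Ks by accepting only
  synonymous substitutions, logged so the realized Ks is known exactly;
* LTR pairs accumulate neutral substitutions for a chosen age at a chosen
  rate;
* allele-level expression counts are generated with planted allele-specific
  effects, and metabolite matrices with planted gene-metabolite
  correlations.

All generators take an integer seed and are bit-reproducible.
"""

from __future__ import annotations

import copy as _copy
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _codons
from ._codons import BASES, CODON_TO_AA, STOP_CODONS, count_sites

_GENE_GAP = 100  # intergenic spacer used when laying out coordinates


# ---------------------------------------------------------------------------
# genome representation
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene on a chromosome; coordinates are 0-based half-open."""

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    ancestral_id: str
    copy_label: str = "1"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimGenome:
    """A genome as an ordered list of (chromosome id, ordered gene list)."""

    genome_id: str
    chromosomes: list[tuple[str, list[GeneModel]]]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for _, g in self.chromosomes)

    def chrom_ids(self) -> list[str]:
        return [cid for cid, _ in self.chromosomes]

    def genes(self):
        for _, glist in self.chromosomes:
            yield from glist

    def gene_table(self) -> pd.DataFrame:
        """Flat table with per-chromosome gene ranks (dense ordinals)."""
        rows = []
        for cid, glist in self.chromosomes:
            for rank, g in enumerate(glist):
                rows.append(
                    (g.gene_id, cid, g.start, g.end, g.strand,
                     g.ancestral_id, g.copy_label, rank)
                )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "start", "end", "strand",
                     "ancestral_id", "copy_label", "rank"],
        )

    def copy(self) -> "SimGenome":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        seen_chrom: set[str] = set()
        seen_gene: set[str] = set()
        for cid, glist in self.chromosomes:
            if cid in seen_chrom:
                raise ValueError(f"duplicate chromosome id {cid!r}")
            seen_chrom.add(cid)
            prev_end = -1
            for g in glist:
                if g.gene_id in seen_gene:
                    raise ValueError(f"duplicate gene id {g.gene_id!r}")
                seen_gene.add(g.gene_id)
                if g.chrom_id != cid:
                    raise ValueError(f"{g.gene_id}: chrom_id mismatch")
                if not g.start < g.end:
                    raise ValueError(f"{g.gene_id}: start >= end")
                if g.start <= prev_end - 1 and g.start < prev_end:
                    raise ValueError(f"{g.gene_id}: overlaps previous gene")
                prev_end = g.end


def _relayout(chrom_id: str, genes: list[GeneModel]) -> list[GeneModel]:
    """Reassign sequential coordinates after a rearrangement, preserving
    gene lengths and order."""
    out = []
    pos = 0
    for g in genes:
        L = g.length
        out.append(replace(g, chrom_id=chrom_id, start=pos, end=pos + L))
        pos += L + _GENE_GAP
    return out


# ---------------------------------------------------------------------------
# evolutionary events
# ---------------------------------------------------------------------------

@dataclass
class WGD:
    """Whole-genome duplication: every chromosome appears twice."""


@dataclass
class Fusion:
    """Concatenate two chromosomes (orientation '-' reverses the second).

    Chromosomes may be referenced by id or by current index; ``None`` lets
    the scenario RNG pick a random distinct pair (and, for orientation, a
    random sign -- real fusions join either chromosome end) at application
    time.
    """

    chrom_a: int | str | None = None
    chrom_b: int | str | None = None
    orientation: str | None = None


@dataclass
class Fission:
    """Split one chromosome before gene rank ``at`` (1 <= at <= n-1)."""

    chrom: int | str | None = None
    at: int | None = None


@dataclass
class Inversion:
    """Reverse gene order and flip strands on ranks [lo, hi)."""

    chrom: int | str | None = None
    lo: int | None = None
    hi: int | None = None


@dataclass
class Loss:
    """Fractionation: drop each gene copy independently with probability
    1 - retention, never deleting the genome's last copy of an
    ancestral gene."""

    retention: float = 0.8


Event = WGD | Fusion | Fission | Inversion | Loss


@dataclass
class EvolutionScenario:
    events: list[Event] = field(default_factory=list)
    seed: int = 0


def _resolve_chrom(genome: SimGenome, ref, rng, exclude: set[int] = frozenset()) -> int:
    if ref is None:
        choices = [i for i in range(genome.n_chromosomes) if i not in exclude]
        if not choices:
            raise ValueError("no chromosome available for random choice")
        return int(rng.choice(choices))
    if isinstance(ref, str):
        ids = genome.chrom_ids()
        if ref not in ids:
            raise KeyError(f"unknown chromosome id {ref!r}")
        return ids.index(ref)
    idx = int(ref)
    if not 0 <= idx < genome.n_chromosomes:
        raise KeyError(f"chromosome index {idx} out of range")
    return idx


def apply_event(genome: SimGenome, event: Event, rng=None) -> SimGenome:
    """Apply one evolutionary event, returning a new genome.

    ``rng`` (numpy Generator or int seed) is required for LOSS and for
    events with unresolved (None) chromosome references.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    g = genome.copy()

    if isinstance(event, WGD):
        new_chroms = []
        for suffix, label in (("A", ".1"), ("B", ".2")):
            for cid, glist in g.chromosomes:
                ncid = cid + suffix
                ngenes = [
                    replace(x, gene_id=x.gene_id + suffix, chrom_id=ncid,
                            copy_label=x.copy_label + label)
                    for x in glist
                ]
                new_chroms.append((ncid, ngenes))
        g.chromosomes = new_chroms
        return g

    if isinstance(event, Fusion):
        ia = _resolve_chrom(g, event.chrom_a, rng)
        ib = _resolve_chrom(g, event.chrom_b, rng, exclude={ia})
        if ia == ib:
            raise ValueError("cannot fuse a chromosome with itself")
        cid_a, genes_a = g.chromosomes[ia]
        cid_b, genes_b = g.chromosomes[ib]
        orientation = event.orientation
        if orientation is None:
            orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            genes_b = [replace(x, strand="-" if x.strand == "+" else "+")
                       for x in reversed(genes_b)]
        elif orientation != "+":
            raise ValueError(f"bad orientation {orientation!r}")
        ncid = f"{cid_a}-{cid_b}"
        fused = _relayout(ncid, genes_a + genes_b)
        chroms = [c for i, c in enumerate(g.chromosomes) if i not in (ia, ib)]
        chroms.insert(min(ia, ib), (ncid, fused))
        g.chromosomes = chroms
        return g

    if isinstance(event, Fission):
        if event.chrom is None:
            splittable = [i for i, (_, gl) in enumerate(g.chromosomes)
                          if len(gl) >= 2]
            if not splittable:
                raise ValueError("no chromosome with >= 2 genes to split")
            ic = int(rng.choice(splittable))
        else:
            ic = _resolve_chrom(g, event.chrom, rng)
        cid, glist = g.chromosomes[ic]
        n = len(glist)
        if n < 2:
            raise ValueError(f"cannot split single-gene chromosome {cid!r}")
        at = event.at if event.at is not None else int(rng.integers(1, n))
        if not 1 <= at <= n - 1:
            raise ValueError(f"breakpoint {at} out of range for {cid!r} ({n} genes)")
        left = _relayout(cid + ".1", glist[:at])
        right = _relayout(cid + ".2", glist[at:])
        g.chromosomes = (
            g.chromosomes[:ic] + [(cid + ".1", left), (cid + ".2", right)]
            + g.chromosomes[ic + 1:]
        )
        return g

    if isinstance(event, Inversion):
        ic = _resolve_chrom(g, event.chrom, rng)
        cid, glist = g.chromosomes[ic]
        n = len(glist)
        if event.lo is None or event.hi is None:
            lo = int(rng.integers(0, n))
            hi = int(rng.integers(lo + 1, n + 1))
        else:
            lo, hi = event.lo, event.hi
        if not (0 <= lo < hi <= n):
            raise ValueError(f"inversion interval [{lo},{hi}) out of range")
        mid = [replace(x, strand="-" if x.strand == "+" else "+")
               for x in reversed(glist[lo:hi])]
        g.chromosomes[ic] = (cid, _relayout(cid, glist[:lo] + mid + glist[hi:]))
        return g

    if isinstance(event, Loss):
        if not 0.0 <= event.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")
        counts = Counter(x.ancestral_id for x in g.genes())
        keep_draws = rng.random(g.n_genes)
        i = 0
        new_chroms = []
        for cid, glist in g.chromosomes:
            kept = []
            for x in glist:
                drop = keep_draws[i] > event.retention
                i += 1
                if drop and counts[x.ancestral_id] > 1:
                    counts[x.ancestral_id] -= 1
                else:
                    kept.append(x)
            new_chroms.append((cid, _relayout(cid, kept)))
        g.chromosomes = [(cid, gl) for cid, gl in new_chroms if gl]
        return g

    raise TypeError(f"unknown event {event!r}")


def evolve(genome: SimGenome, scenario: EvolutionScenario) -> SimGenome:
    """Apply a scenario's events in order with its own RNG stream."""
    rng = np.random.default_rng(scenario.seed)
    g = genome
    for ev in scenario.events:
        g = apply_event(g, ev, rng)
    return g


# ---------------------------------------------------------------------------
# ancestor construction and lineage evolution
# ---------------------------------------------------------------------------

def make_ancestor(n_chrom: int, genes_per_chrom: int, seed: int) -> SimGenome:
    """An ancestral genome with ``n_chrom`` chromosomes of
    ``genes_per_chrom`` ordered genes; ancestral_id == gene_id."""
    if n_chrom < 1 or genes_per_chrom < 1:
        raise ValueError("n_chrom and genes_per_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = []
    for c in range(1, n_chrom + 1):
        cid = f"chr{c}"
        lengths = rng.integers(1000, 5001, size=genes_per_chrom)
        strands = rng.random(genes_per_chrom) < 0.5
        genes = []
        pos = 0
        for i in range(genes_per_chrom):
            gid = f"g{c}_{i + 1:04d}"
            genes.append(GeneModel(gid, cid, pos, pos + int(lengths[i]),
                                   "+" if strands[i] else "-", gid))
            pos += int(lengths[i]) + _GENE_GAP
        chroms.append((cid, genes))
    return SimGenome("ancestor", chroms)


@dataclass
class TruthHomology:
    """Ground-truth homology keyed by shared ancestral_id."""

    genome_a: str
    genome_b: str
    genes_a: dict[str, str]  # gene_id -> ancestral_id
    genes_b: dict[str, str]

    def copy_counts(self, genome: str) -> Counter:
        genes = self._genes(genome)
        return Counter(genes.values())

    def _genes(self, genome: str) -> dict[str, str]:
        if genome == self.genome_a:
            return self.genes_a
        if genome == self.genome_b:
            return self.genes_b
        raise KeyError(genome)

    def cross_pairs(self) -> pd.DataFrame:
        """All homologous pairs between the two genomes (one row per pair)."""
        by_anc: dict[str, list[str]] = {}
        for gid, aid in self.genes_a.items():
            by_anc.setdefault(aid, []).append(gid)
        rows = []
        for gid_b, aid in self.genes_b.items():
            for gid_a in by_anc.get(aid, ()):
                rows.append((gid_a, gid_b))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])

    def within_pairs(self, genome: str) -> pd.DataFrame:
        """Distinct homologous pairs among copies inside one genome."""
        by_anc: dict[str, list[str]] = {}
        for gid, aid in self._genes(genome).items():
            by_anc.setdefault(aid, []).append(gid)
        rows = []
        for gids in by_anc.values():
            gids = sorted(gids)
            for i in range(len(gids)):
                for j in range(i + 1, len(gids)):
                    rows.append((gids[i], gids[j]))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])

    def is_homolog(self, gid_a: str, gid_b: str) -> bool:
        all_genes = {**self.genes_a, **self.genes_b}
        return all_genes.get(gid_a) is not None and \
            all_genes.get(gid_a) == all_genes.get(gid_b)


def _prefix_genome(genome: SimGenome, gid: str) -> SimGenome:
    g = genome.copy()
    g.genome_id = gid
    g.chromosomes = [
        (f"{gid}_{cid}",
         [replace(x, gene_id=f"{gid}_{x.gene_id}", chrom_id=f"{gid}_{cid}")
          for x in glist])
        for cid, glist in g.chromosomes
    ]
    return g


def evolve_lineages(
    ancestor: SimGenome,
    scenario_a: EvolutionScenario,
    scenario_b: EvolutionScenario,
    ids: tuple[str, str] = ("A", "B"),
) -> tuple[SimGenome, SimGenome, TruthHomology]:
    """Evolve two lineages from a common ancestor and return both extant
    genomes plus the full truth homology table."""
    ga = evolve(_prefix_genome(ancestor, ids[0]), scenario_a)
    gb = evolve(_prefix_genome(ancestor, ids[1]), scenario_b)
    truth = TruthHomology(
        ids[0], ids[1],
        {x.gene_id: x.ancestral_id for x in ga.genes()},
        {x.gene_id: x.ancestral_id for x in gb.genes()},
    )
    return ga, gb, truth


def betel_palm_scenario(retention: float = 0.8, n_inversions: int = 3,
                     seed: int = 0) -> EvolutionScenario:
    """The betel-palm-like lineage: WGD, 2 fissions + 5 fusions (n 6->12->9),
    then a second WGD, 1 fission + 3 fusions (n 18->16), with fractionation
    after each WGD."""
    ev: list[Event] = [WGD(), Fission(), Fission()]
    ev += [Fusion() for _ in range(5)]
    ev += [Inversion() for _ in range(n_inversions)]
    ev += [Loss(retention), WGD(), Fission(), Fusion(), Fusion(), Fusion()]
    ev += [Inversion() for _ in range(n_inversions)]
    ev += [Loss(retention)]
    return EvolutionScenario(ev, seed)


def duckweed_like_scenario_b(retention: float = 0.8, n_inversions: int = 3,
                             seed: int = 1) -> EvolutionScenario:
    """A second monocot lineage with the same two WGD rounds but its own
    fusion/fission history (6 -> 12 -> 11 -> 22 -> 20 chromosomes). The
    real outgroup's history is unknown; this is a free choice that keeps
    the two lineages' fusion junctions independent."""
    ev: list[Event] = [WGD(), Fission(), Fusion(), Fusion()]
    ev += [Inversion() for _ in range(n_inversions)]
    ev += [Loss(retention), WGD(), Fusion(), Fusion()]
    ev += [Inversion() for _ in range(n_inversions)]
    ev += [Loss(retention)]
    return EvolutionScenario(ev, seed)


@dataclass
class StandardSim:
    ancestor: SimGenome
    genome_a: SimGenome
    genome_b: SimGenome
    truth: TruthHomology
    scenario_a: EvolutionScenario
    scenario_b: EvolutionScenario


def standard_simulation(seed: int = 20250502, n_chrom: int = 6,
                        genes_per_chrom: int = 200, retention: float = 0.8,
                        n_inversions: int = 3) -> StandardSim:
    """The default study conditions: a 6-chromosome ancestor evolved through
    two WGD rounds in each of two lineages (4:4 expected block multiplicity),
    with fusions, fissions, inversions and fractionation."""
    anc = make_ancestor(n_chrom, genes_per_chrom, seed)
    sa = betel_palm_scenario(retention, n_inversions, seed=seed + 1)
    sb = duckweed_like_scenario_b(retention, n_inversions, seed=seed + 2)
    ga, gb, truth = evolve_lineages(anc, sa, sb)
    return StandardSim(anc, ga, gb, truth, sa, sb)


# ---------------------------------------------------------------------------
# sequence-pair simulators
# ---------------------------------------------------------------------------

@dataclass
class SeqSimParams:
    length: int  # codons (Ks pairs) or bp (LTR pairs)
    ks_target: float | None = None
    age_years: float | None = None
    mu: float = 5.6e-10
    seed: int = 0


def _mutate_synonymous(codons: list[str], n_events: int, rng) -> int:
    """Apply ``n_events`` accepted synonymous substitutions in place."""
    n = len(codons)
    applied = 0
    while applied < n_events:
        ci = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        cur = codons[ci]
        base = BASES[int(rng.integers(0, 4))]
        if base == cur[pos]:
            continue
        alt = cur[:pos] + base + cur[pos + 1:]
        if alt in STOP_CODONS or CODON_TO_AA[alt] != CODON_TO_AA[cur]:
            continue
        codons[ci] = alt
        applied += 1
    return applied


def simulate_codon_pair(params: SeqSimParams) -> tuple[str, str, float]:
    """A pair of in-frame CDS diverged to a target Ks.

    A random stop-free ancestral sequence receives Poisson(ks_target * S)
    synonymous substitution events split randomly between the two
    descendants (S = the ancestor's synonymous sites). The returned truth
    is the logged event count divided by the mean synonymous-site count of
    the two final sequences, i.e. the quantity a Ks estimator targets.
    """
    if params.ks_target is None or params.ks_target < 0:
        raise ValueError("ks_target must be >= 0")
    if params.length < 10:
        raise ValueError("need at least 10 codons")
    rng = np.random.default_rng(params.seed)
    codons_a = _codons.random_sense_codons(rng, params.length)
    s_anc, _ = count_sites("".join(codons_a))
    n_events = int(rng.poisson(params.ks_target * s_anc))
    to_a = int(rng.binomial(n_events, 0.5))
    codons_b = list(codons_a)
    _mutate_synonymous(codons_a, to_a, rng)
    _mutate_synonymous(codons_b, n_events - to_a, rng)
    seq_a, seq_b = "".join(codons_a), "".join(codons_b)
    s_mean = (count_sites(seq_a)[0] + count_sites(seq_b)[0]) / 2.0
    return seq_a, seq_b, n_events / s_mean


@dataclass
class LTRPair:
    element_id: str
    ltr5: str
    ltr3: str
    d_truth: float  # substitution events per site, both copies combined
    age_years: float
    mu: float


def simulate_ltr_element(age_years: float, mu: float, length: int,
                         seed: int = 0, element_id: str = "ltr1") -> LTRPair:
    """Two LTR copies, identical at insertion, each accumulating neutral
    substitutions at rate ``mu`` per site per year for ``age_years``.
    Expected pairwise divergence is 2 * mu * age_years."""
    if age_years < 0:
        raise ValueError("age must be >= 0")
    if mu <= 0 or length <= 0:
        raise ValueError("mu and length must be positive")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, size=length)
    copies = []
    n_total = 0
    for _ in range(2):
        seq = anc.copy()
        n = int(rng.poisson(mu * age_years * length))
        n_total += n
        pos = rng.integers(0, length, size=n)
        shift = rng.integers(1, 4, size=n)
        for p, s in zip(pos, shift):
            seq[p] = (seq[p] + s) % 4
        copies.append("".join("ACGT"[b] for b in seq))
    return LTRPair(element_id, copies[0], copies[1], n_total / length,
                   age_years, mu)


# ---------------------------------------------------------------------------
# CDS assignment for allelic-pair analyses
# ---------------------------------------------------------------------------

def make_cds(genomes: list[SimGenome], seed: int = 0,
             min_codons: int = 100, max_codons: int = 300) -> dict[str, str]:
    """One random stop-free CDS per ancestral gene, shared verbatim by all
    of its surviving copies across the given genomes."""
    rng = np.random.default_rng(seed)
    per_anc: dict[str, str] = {}
    cds: dict[str, str] = {}
    for g in genomes:
        for x in g.genes():
            if x.ancestral_id not in per_anc:
                n = int(rng.integers(min_codons, max_codons + 1))
                per_anc[x.ancestral_id] = "".join(
                    _codons.random_sense_codons(rng, n))
            cds[x.gene_id] = per_anc[x.ancestral_id]
    return cds


def mutate_cds_fraction(cds: dict[str, str], gene_ids, fraction: float,
                        n_sub: int = 2, seed: int = 0) -> set[str]:
    """Give a random ``fraction`` of the listed genes 1..n_sub point
    substitutions (in place); returns the edited gene-id set."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    k = int(round(fraction * len(gene_ids)))
    chosen = set(rng.choice(gene_ids, size=k, replace=False)) if k else set()
    for gid in sorted(chosen):
        seq = list(cds[gid])
        for _ in range(int(rng.integers(1, n_sub + 1))):
            p = int(rng.integers(0, len(seq)))
            alts = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alts[int(rng.integers(0, 3))]
        cds[gid] = "".join(seq)
    return chosen


def clone_as_haplotypes(genome: SimGenome, seed: int = 0) -> tuple[
        SimGenome, SimGenome, pd.DataFrame]:
    """Duplicate a genome into two near-identical haplotypes (H1/H2) and
    return the gene-id pairing table."""
    h1 = _prefix_genome(genome, "H1")
    h2 = _prefix_genome(genome, "H2")
    pairs = pd.DataFrame({
        "gene_h1": [x.gene_id for x in h1.genes()],
        "gene_h2": [x.gene_id for x in h2.genes()],
    })
    return h1, h2, pairs


# ---------------------------------------------------------------------------
# expression simulator
# ---------------------------------------------------------------------------

TWELVE_TISSUES = (
    "root", "stem", "leaf", "bract", "sepal", "petal", "stamen",
    "pistil", "receptacle", "male_flower", "female_flower", "peduncle",
)


@dataclass
class ExprSimParams:
    n_pairs: int = 200
    tissues: tuple[str, ...] = TWELVE_TISSUES
    replicates: int = 3
    ase_fraction: float = 0.1
    effect: float = 4.0
    noise_sd: float = 0.1  # sd of log2-scale multiplicative noise
    library_size: float = 5e6
    ase_tissues: tuple[str, ...] | None = None  # None = all tissues
    tissue_sd: float = 0.4  # between-tissue baseline variation (log2)
    deg_fraction: float = 0.0  # genes given a tissue-specific shift
    deg_effect: float = 1.0
    deg_tissue: str | None = None
    seed: int = 0


@dataclass
class ExpressionSim:
    counts: pd.DataFrame  # genes x samples, integer counts
    lengths: pd.Series
    samples: pd.DataFrame  # sample, tissue, replicate, haplotype
    pairs: pd.DataFrame  # gene_h1, gene_h2, is_ase, ase_direction
    truth_ase: set[tuple[str, str]]
    truth_deg: set[str]


def simulate_expression(params: ExprSimParams,
                        pairs: pd.DataFrame | None = None) -> ExpressionSim:
    """Allele-level expression counts for gene pairs across tissues.

    Expression is a gamma-distributed per-pair baseline, a log-normal
    per-tissue multiplier, a planted allele fold change on the ASE subset,
    and log-normal replicate noise; counts are Poisson draws scaled to the
    library size. Both alleles of a pair share one gene length.
    """
    if not 0.0 <= params.ase_fraction <= 1.0:
        raise ValueError("ase_fraction must be in [0, 1]")
    if params.replicates < 2:
        raise ValueError("need >= 2 replicates")
    if params.ase_fraction > 0 and params.effect <= 1.0 and params.effect != 1.0:
        raise ValueError("planted effect must be > 1")
    rng = np.random.default_rng(params.seed)

    if pairs is None:
        pairs = pd.DataFrame({
            "gene_h1": [f"H1_g{i:04d}" for i in range(params.n_pairs)],
            "gene_h2": [f"H2_g{i:04d}" for i in range(params.n_pairs)],
        })
    pairs = pairs[["gene_h1", "gene_h2"]].copy()
    n = len(pairs)
    tissues = list(params.tissues)
    n_t, n_r = len(tissues), params.replicates

    lengths_pair = rng.integers(500, 3001, size=n).astype(float)
    baseline = rng.gamma(shape=1.5, scale=40.0, size=n)
    tissue_mult = 2.0 ** rng.normal(0.0, params.tissue_sd, size=(n, n_t))

    # planted tissue-differential genes (both alleles shifted together)
    n_deg = int(round(params.deg_fraction * n))
    deg_idx = rng.choice(n, size=n_deg, replace=False) if n_deg else np.array([], int)
    deg_tissue = params.deg_tissue or tissues[0]
    tissue_mult[deg_idx, tissues.index(deg_tissue)] *= params.deg_effect

    # planted allele-specific pairs
    n_ase = int(round(params.ase_fraction * n)) if params.effect != 1.0 else 0
    ase_idx = rng.choice(n, size=n_ase, replace=False) if n_ase else np.array([], int)
    direction = np.zeros(n, int)  # +1: H1 up, -1: H2 up
    direction[ase_idx] = rng.choice([1, -1], size=n_ase)
    ase_t_idx = [tissues.index(t) for t in (params.ase_tissues or tissues)]

    allele_fc = np.ones((n, n_t, 2))
    for i in ase_idx:
        a = 0 if direction[i] > 0 else 1
        allele_fc[i, ase_t_idx, a] = params.effect

    # expression (TPM-scale) per gene x tissue x replicate x allele
    base = baseline[:, None, None, None] * tissue_mult[:, :, None, None]
    noise = 2.0 ** rng.normal(0.0, params.noise_sd, size=(n, n_t, n_r, 2))
    expr = base * allele_fc[:, :, None, :] * noise

    sample_rows = []
    cols = {}
    gene_ids = {0: pairs["gene_h1"].to_numpy(), 1: pairs["gene_h2"].to_numpy()}
    all_genes = np.concatenate([gene_ids[0], gene_ids[1]])
    lib_jitter = 2.0 ** rng.normal(0.0, 0.1, size=(n_t, n_r, 2))
    for ti, t in enumerate(tissues):
        for r in range(n_r):
            for hi, hap in enumerate(("H1", "H2")):
                sid = f"{t}_r{r + 1}_{hap}"
                sample_rows.append((sid, t, r + 1, hap))
                rate = expr[:, ti, r, hi] * lengths_pair / 1000.0
                scale = params.library_size * lib_jitter[ti, r, hi] / rate.sum()
                counts_h = rng.poisson(rate * scale)
                col = np.zeros(2 * n, dtype=np.int64)
                col[hi * n:(hi + 1) * n] = counts_h
                cols[sid] = col
    counts = pd.DataFrame(cols, index=all_genes)
    lengths = pd.Series(np.concatenate([lengths_pair, lengths_pair]),
                        index=all_genes)
    samples = pd.DataFrame(sample_rows,
                           columns=["sample", "tissue", "replicate", "haplotype"])
    pairs["is_ase"] = False
    pairs.loc[pairs.index[ase_idx], "is_ase"] = True
    pairs["ase_direction"] = direction
    truth_ase = {tuple(r) for r in
                 pairs.loc[pairs["is_ase"], ["gene_h1", "gene_h2"]].to_numpy()}
    truth_deg = {g for i in deg_idx for g in (gene_ids[0][i], gene_ids[1][i])}
    return ExpressionSim(counts, lengths, samples, pairs, truth_ase, truth_deg)


# ---------------------------------------------------------------------------
# metabolome simulator
# ---------------------------------------------------------------------------

METABOLITE_CLASSES = (
    "alkaloid", "flavonoid", "phenolic_acid", "amino_acid",
    "lipid", "terpenoid", "organic_acid", "others",
)


@dataclass
class MetSimParams:
    n_metabolites: int = 100
    linked_fraction: float = 0.2
    target_r: float = 0.9
    seed: int = 0


@dataclass
class MetabolomeSim:
    intensities: pd.DataFrame  # metabolites x samples
    truth_links: pd.DataFrame  # metabolite, gene, sign
    classes: pd.Series
    groups: pd.Series  # sample -> tissue


def simulate_metabolome(expression: pd.DataFrame, tissues: pd.Series,
                        params: MetSimParams) -> MetabolomeSim:
    """Metabolite intensities over the expression samples.

    A ``linked_fraction`` of metabolites are noisy linear functions (on the
    log2 scale) of a randomly chosen partner gene's expression, mixed so the
    planted |Pearson r| on log2 values is ~``target_r`` with a random sign;
    the rest are independent log-normal noise.
    """
    if not 0.0 <= abs(params.target_r) <= 1.0:
        raise ValueError("|target_r| must be <= 1")
    rng = np.random.default_rng(params.seed)
    X = np.log2(expression.to_numpy(dtype=float) + 1.0)
    sd = X.std(axis=1)
    usable = np.flatnonzero(sd > 1e-8)
    if usable.size == 0:
        raise ValueError("no gene with variance in the expression matrix")
    n_samp = X.shape[1]
    m = params.n_metabolites
    n_link = int(round(params.linked_fraction * m))
    link_gene_idx = rng.choice(usable, size=n_link, replace=n_link > usable.size)
    signs = rng.choice([1.0, -1.0], size=n_link)

    r = abs(params.target_r)
    log_met = rng.normal(0.0, 1.0, size=(m, n_samp))
    rows = []
    for k in range(n_link):
        gi = link_gene_idx[k]
        z = (X[gi] - X[gi].mean()) / X[gi].std()
        log_met[k] = signs[k] * (r * z) + np.sqrt(max(0.0, 1 - r * r)) * log_met[k]
        rows.append((f"met{k + 1:03d}", expression.index[gi],
                     "positive" if signs[k] > 0 else "negative"))
    met_ids = [f"met{i + 1:03d}" for i in range(m)]
    intensities = pd.DataFrame(2.0 ** (log_met + 10.0), index=met_ids,
                               columns=expression.columns)
    classes = pd.Series(rng.choice(METABOLITE_CLASSES, size=m), index=met_ids)
    truth = pd.DataFrame(rows, columns=["metabolite", "gene", "sign"])
    groups = pd.Series(tissues.to_numpy(), index=expression.columns,
                       name="tissue")
    return MetabolomeSim(intensities, truth, classes, groups)


# ---------------------------------------------------------------------------
# fixture output
# ---------------------------------------------------------------------------

def write_fixtures(directory, *, genome_a: SimGenome | None = None,
                   genome_b: SimGenome | None = None,
                   truth: TruthHomology | None = None,
                   cds: dict[str, str] | None = None,
                   expression: ExpressionSim | None = None,
                   metabolome: MetabolomeSim | None = None,
                   scenarios: dict | None = None) -> list[Path]:
    """Write the standard on-disk fixture set (GFF3 / FASTA / TSV / JSON).

    GFF3 coordinates are written 1-based inclusive; internal coordinates
    are 0-based half-open (start+1 on write).
    """
    from . import io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path):
        written.append(path)
        return path

    for tag, g in (("A", genome_a), ("B", genome_b)):
        if g is None:
            continue
        pio.write_gff3(g.gene_table(), _w(directory / f"genes_{tag}.gff3"))
        if cds:
            sub = {x.gene_id: cds[x.gene_id] for x in g.genes() if x.gene_id in cds}
            pio.write_fasta(sub, _w(directory / f"cds_{tag}.fasta"))
    if truth is not None:
        truth.cross_pairs().to_csv(_w(directory / "homology.tsv"),
                                   sep="\t", index=False)
    if expression is not None:
        expression.counts.rename_axis("gene").to_csv(
            _w(directory / "counts.tsv"), sep="\t")
        expression.lengths.rename("length").rename_axis("gene").to_csv(
            _w(directory / "lengths.tsv"), sep="\t")
        expression.samples.to_csv(_w(directory / "samples.tsv"),
                                  sep="\t", index=False)
    if metabolome is not None:
        metabolome.intensities.rename_axis("metabolite").to_csv(
            _w(directory / "metabolites.tsv"), sep="\t")
    truth_json: dict = {}
    if scenarios:
        truth_json["scenarios"] = scenarios
    if truth is not None:
        truth_json["copy_counts"] = {
            truth.genome_a: dict(truth.copy_counts(truth.genome_a)),
            truth.genome_b: dict(truth.copy_counts(truth.genome_b)),
        }
        truth_json["gene_ancestry"] = {
            truth.genome_a: truth.genes_a, truth.genome_b: truth.genes_b}
    if expression is not None:
        truth_json["ase_pairs"] = sorted(map(list, expression.truth_ase))
        truth_json["deg_genes"] = sorted(expression.truth_deg)
    if metabolome is not None:
        truth_json["metabolite_links"] = metabolome.truth_links.to_dict("records")
    if truth_json:
        path = _w(directory / "truth.json")
        path.write_text(json.dumps(truth_json, indent=1))
    return written


def scenario_to_dict(sc: EvolutionScenario) -> dict:
    return {
        "seed": sc.seed,
        "events": [
            {"type": type(ev).__name__, **{k: v for k, v in ev.__dict__.items()}}
            for ev in sc.events
        ],
    }
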
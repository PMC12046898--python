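"""Collinear synteny-block detection between two gene orders.

Homolog pairs (from an external similarity search, or from simulator truth)
become anchors in gene-rank space; blocks are maximal collinear anchor
chains extracted per chromosome pair by dynamic programming, greedily
best-first. Downstream the module measures per-genome block multiplicity
(the 4:4 signal of two WGD rounds in two lineages) and derives one-to-one
allelic gene pairs with CDS identity classes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .simulate import SimGenome


@dataclass(frozen=True)
class Anchor:
    """One homologous gene pair in rank space (the dot of a dotplot)."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass
class SyntenyBlock:
    """A collinear chain of anchors; rank intervals are half-open."""

    block_id: int
    genome_a: str
    genome_b: str
    chrom_a: str
    lo_a: int
    hi_a: int
    chrom_b: str
    lo_b: int
    hi_b: int
    orientation: str
    anchors: list[Anchor] = field(default_factory=list)

    @property
    def score(self) -> int:
        return len(self.anchors)


def _as_gene_table(genes) -> pd.DataFrame:
    if isinstance(genes, SimGenome):
        return genes.gene_table()
    df = genes.copy()
    if "rank" not in df.columns:
        df = df.sort_values(["chrom", "start"], kind="stable")
        df["rank"] = df.groupby("chrom", sort=False).cumcount()
    return df


def build_anchors(genes_a, genes_b, homology: pd.DataFrame,
                  genome_a: str = "A", genome_b: str = "B") -> list[Anchor]:
    """One anchor per homolog pair, with dense per-chromosome gene ranks.

    ``genes_a``/``genes_b`` are SimGenomes or tables with gene_id, chrom,
    start; ``homology`` has columns gene_a, gene_b. Unknown or duplicate
    gene ids raise with the offending id.
    """
    if isinstance(genes_a, SimGenome):
        genome_a = genes_a.genome_id
    if isinstance(genes_b, SimGenome):
        genome_b = genes_b.genome_id
    ta, tb = _as_gene_table(genes_a), _as_gene_table(genes_b)
    maps = []
    for t in (ta, tb):
        dup = t["gene_id"][t["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene id {dup.iloc[0]!r}")
        maps.append(t.set_index("gene_id")[["chrom", "rank"]])
    ma, mb = maps
    anchors = []
    for ga, gb in homology[["gene_a", "gene_b"]].itertuples(index=False):
        if ga not in ma.index:
            raise KeyError(f"gene id {ga!r} not found in genome {genome_a}")
        if gb not in mb.index:
            raise KeyError(f"gene id {gb!r} not found in genome {genome_b}")
        ra, rb = ma.loc[ga], mb.loc[gb]
        anchors.append(Anchor(ga, gb, ra["chrom"], rb["chrom"],
                              int(ra["rank"]), int(rb["rank"])))
    return anchors


def _best_chain(ra: np.ndarray, rb: np.ndarray, max_gap: int):
    """Highest-score collinear chain over anchor arrays; returns
    (indices, orientation). Ties prefer '+', then the chain found first in
    (rank_a, rank_b) order."""
    best_idx: list[int] = []
    best_orient = "+"
    order0 = np.lexsort((rb, ra))
    for orient, sgn in (("+", 1), ("-", -1)):
        order = order0 if sgn == 1 else np.lexsort((-rb, ra))
        a, b = ra[order], sgn * rb[order]
        m = len(a)
        dp = np.ones(m, dtype=np.int64)
        parent = np.full(m, -1, dtype=np.int64)
        for i in range(1, m):
            ok = (a[:i] < a[i]) & (a[i] - a[:i] <= max_gap) \
                & (b[:i] < b[i]) & (b[i] - b[:i] <= max_gap)
            if ok.any():
                cand = np.where(ok, dp[:i], 0)
                j = int(np.argmax(cand))
                if cand[j] + 1 > dp[i]:
                    dp[i] = cand[j] + 1
                    parent[i] = j
        end = int(np.argmax(dp))
        chain = []
        k = end
        while k >= 0:
            chain.append(int(order[k]))
            k = int(parent[k])
        chain.reverse()
        if len(chain) > len(best_idx):
            best_idx, best_orient = chain, orient
    return best_idx, best_orient


def chain_anchors(anchors: list[Anchor], max_gap: int = 25,
                  min_block_anchors: int = 5,
                  genome_a: str = "A", genome_b: str = "B") -> list[SyntenyBlock]:
    """Extract synteny blocks by greedy best-first collinear chaining.

    Per chromosome pair, the best chain (score = anchor count; successive
    anchors strictly increasing in rank_a and monotone in rank_b with both
    rank gaps <= max_gap) is removed repeatedly until the best falls below
    ``min_block_anchors``. Each anchor ends up in at most one block.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_block_anchors < 2:
        raise ValueError("min_block_anchors must be >= 2")
    groups: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.chrom_a, a.chrom_b)].append(a)
    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(groups):
        pool = groups[(ca, cb)]
        while len(pool) >= min_block_anchors:
            ra = np.array([x.rank_a for x in pool])
            rb = np.array([x.rank_b for x in pool])
            idx, orient = _best_chain(ra, rb, max_gap)
            if len(idx) < min_block_anchors:
                break
            chain = [pool[i] for i in idx]
            bs = [x.rank_b for x in chain]
            blocks.append(SyntenyBlock(
                0, genome_a, genome_b, ca,
                chain[0].rank_a, chain[-1].rank_a + 1,
                cb, min(bs), max(bs) + 1, orient, chain))
            used = set(idx)
            pool = [x for i, x in enumerate(pool) if i not in used]
    blocks.sort(key=lambda blk: (blk.chrom_a, blk.lo_a, blk.chrom_b, blk.lo_b))
    for i, blk in enumerate(blocks):
        blk.block_id = i
    return blocks


def blocks_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.block_id, b.chrom_a, b.lo_a, b.hi_a, b.chrom_b, b.lo_b, b.hi_b,
          b.orientation, b.score) for b in blocks],
        columns=["block_id", "chrom_a", "start_rank_a", "end_rank_a",
                 "chrom_b", "start_rank_b", "end_rank_b", "orientation",
                 "n_anchors"])


def anchors_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = [(b.block_id, a.gene_a, a.gene_b, a.chrom_a, a.chrom_b,
             a.rank_a, a.rank_b)
            for b in blocks for a in b.anchors]
    return pd.DataFrame(rows, columns=["block_id", "gene_a", "gene_b",
                                       "chrom_a", "chrom_b", "rank_a", "rank_b"])


@dataclass
class MultiplicityProfile:
    """Per-genome window coverage multiplicity and its mode."""

    window: int
    counts: dict[str, pd.DataFrame]  # genome -> (chrom, window_start, n_blocks)
    modal: dict[str, int]

    @property
    def ratio(self) -> tuple[int, ...]:
        return tuple(self.modal[g] for g in sorted(self.modal))


def block_multiplicity(blocks: list[SyntenyBlock],
                       window: int = 20) -> MultiplicityProfile:
    """Slide non-overlapping rank windows over each genome and count the
    distinct blocks covering (fully containing) each; the mode over covered
    windows is the syntenic copy number of that genome's regions in the
    other genome. Containment, rather than mere overlap, makes the count a
    local copy number: fragmented remnants of a heavily fractionated copy
    no longer register."""
    if not blocks:
        raise ValueError("no blocks given")
    sides = {
        blocks[0].genome_a: [(b.chrom_a, b.lo_a, b.hi_a) for b in blocks],
        blocks[0].genome_b: [(b.chrom_b, b.lo_b, b.hi_b) for b in blocks],
    }
    counts: dict[str, pd.DataFrame] = {}
    modal: dict[str, int] = {}
    for genome, ivals in sides.items():
        chrom_len: dict[str, int] = defaultdict(int)
        for chrom, _, hi in ivals:
            chrom_len[chrom] = max(chrom_len[chrom], hi)
        rows = []
        for chrom in sorted(chrom_len):
            for w0 in range(0, chrom_len[chrom], window):
                w1 = w0 + window
                n = sum(1 for c, lo, hi in ivals
                        if c == chrom and lo <= w0 and hi >= w1)
                rows.append((chrom, w0, n))
        df = pd.DataFrame(rows, columns=["chrom", "window_start", "n_blocks"])
        covered = df.loc[df["n_blocks"] > 0, "n_blocks"]
        modal[genome] = int(covered.mode().iloc[0]) if len(covered) else 0
        counts[genome] = df
    return MultiplicityProfile(window, counts, modal)


@dataclass
class AllelicPair:
    gene_h1: str
    gene_h2: str
    block_id: int
    cds_identity: float
    identity_class: str  # identical / similar / diverged


_ALIGNER = PairwiseAligner(mode="global", match_score=1, mismatch_score=-1,
                           open_gap_score=-2, extend_gap_score=-2)


def cds_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from global alignment (match +1, mismatch -1,
    gap -2): identical columns / alignment length * 100."""
    if seq_a == seq_b:
        return 100.0
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    c = aln.counts()
    return 100.0 * c.identities / aln.length


def find_allelic_pairs(blocks: list[SyntenyBlock], cds_h1: dict[str, str],
                       cds_h2: dict[str, str],
                       similar_threshold: float = 80.0) -> list[AllelicPair]:
    """One-to-one allelic gene pairs from blocks between two haplotypes.

    Blocks are accepted best-score-first, skipping any block whose rank
    interval overlaps an accepted block on either haplotype (keeping the
    single best block per region); anchors of accepted blocks become pairs,
    each gene used at most once. Identity class: identical (100%), similar
    (>= threshold), diverged.
    """
    order = sorted(blocks, key=lambda b: (-b.score, b.chrom_a, b.lo_a,
                                          b.chrom_b, b.lo_b))
    taken_a: dict[str, list[tuple[int, int]]] = defaultdict(list)
    taken_b: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def _free(taken, chrom, lo, hi):
        return all(hi <= l or lo >= h for l, h in taken[chrom])

    accepted = []
    for b in order:
        if _free(taken_a, b.chrom_a, b.lo_a, b.hi_a) and \
                _free(taken_b, b.chrom_b, b.lo_b, b.hi_b):
            accepted.append(b)
            taken_a[b.chrom_a].append((b.lo_a, b.hi_a))
            taken_b[b.chrom_b].append((b.lo_b, b.hi_b))
    accepted.sort(key=lambda b: (b.chrom_a, b.lo_a))

    pairs: list[AllelicPair] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for b in accepted:
        for a in b.anchors:
            if a.gene_a in used_a or a.gene_b in used_b:
                continue
            if a.gene_a not in cds_h1:
                raise KeyError(f"no CDS for gene {a.gene_a!r}")
            if a.gene_b not in cds_h2:
                raise KeyError(f"no CDS for gene {a.gene_b!r}")
            ident = cds_identity(cds_h1[a.gene_a], cds_h2[a.gene_b])
            klass = ("identical" if ident == 100.0
                     else "similar" if ident >= similar_threshold
                     else "diverged")
            pairs.append(AllelicPair(a.gene_a, a.gene_b, b.block_id,
                                     ident, klass))
            used_a.add(a.gene_a)
            used_b.add(a.gene_b)
    return pairs


def allelic_pairs_table(pairs: list[AllelicPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_h1, p.gene_h2, p.block_id, p.cds_identity, p.identity_class)
         for p in pairs],
        columns=["gene_h1", "gene_h2", "block_id", "identity_pct", "class"])


def identity_class_fractions(pairs: list[AllelicPair]) -> dict[str, float]:
    """Fraction of pairs per identity class (the identical/similar split)."""
    n = len(pairs)
    c = Counter(p.identity_class for p in pairs)
    return {k: c.get(k, 0) / n for k in ("identical", "similar", "diverged")}
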
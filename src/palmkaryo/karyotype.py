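"""Ancestral karyotype reconstruction and chromosome-event accounting.

Synteny blocks between two lineages that share the same WGD history are
grouped into ancestral chromosomes ("colors") as connected components of a
block-segment graph; extant chromosomes are painted by ancestral group;
chromosome counts are propagated through WGD / fusion / fission scenarios;
and fusion/fission totals are estimated back from a painting by junction
counting with parsimony over epochs.

Group inference is intended for cross-genome blocks: fusion junctions fixed
in one lineage before its last WGD are duplicated there and so are spanned
by that genome's self-synteny, which would merge two ancestral groups into
one component; the partner lineage, whose junctions differ, breaks blocks at
exactly those points.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .simulate import SimGenome
from .synteny import SyntenyBlock


@dataclass
class AncestralGroup:
    """One ancestral chromosome: connected block segments across genomes."""

    group_id: int
    segments: list[tuple[str, str, int, int]]  # genome, chrom, lo, hi
    total_genes: int


@dataclass
class Segment:
    lo: int
    hi: int
    group_id: int

    @property
    def n_genes(self) -> int:
        return self.hi - self.lo


@dataclass
class ChromosomePainting:
    """Ordered ancestral-group segments along each chromosome."""

    genome_id: str
    segments: dict[str, list[Segment]]
    coverage: float

    @property
    def n_chromosomes(self) -> int:
        return len(self.segments)

    def table(self) -> pd.DataFrame:
        rows = [(c, s.lo, s.hi, s.group_id)
                for c, segs in self.segments.items() for s in segs]
        return pd.DataFrame(rows, columns=["chrom", "seg_start_rank",
                                           "seg_end_rank", "group_id"])


@dataclass
class Epoch:
    """One round of the scenario: an optional WGD followed by a batch of
    fissions and fusions (order within the batch does not affect counts)."""

    wgd: bool = False
    fissions: int = 0
    fusions: int = 0


@dataclass
class KaryotypeScenario:
    n0: int
    epochs: list[Epoch] = field(default_factory=list)

    @property
    def total_fusions(self) -> int:
        return sum(e.fusions for e in self.epochs)

    @property
    def total_fissions(self) -> int:
        return sum(e.fissions for e in self.epochs)


@dataclass
class EventAccounting:
    n0: int
    steps: list[tuple[str, int]]  # (event, chromosome count after it)
    n_final: int


def event_accounting(n0: int, scenario: KaryotypeScenario) -> EventAccounting:
    """Propagate the chromosome count through a scenario: WGD doubles it,
    each fission adds 1, each fusion removes 1, in epoch order."""
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    n = n0
    steps: list[tuple[str, int]] = []
    for e in scenario.epochs:
        if e.fissions < 0 or e.fusions < 0:
            raise ValueError("event counts must be non-negative")
        if e.wgd:
            n *= 2
            steps.append(("WGD", n))
        n += e.fissions
        if e.fissions:
            steps.append((f"+{e.fissions} fissions", n))
        n -= e.fusions
        if e.fusions:
            steps.append((f"-{e.fusions} fusions", n))
        if n < 1:
            raise ValueError(f"infeasible scenario: chromosome count {n} < 1")
    return EventAccounting(n0, steps, n)


# ---------------------------------------------------------------------------
# group inference and painting
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last = -1
    for lo, hi in sorted(intervals):
        lo = max(lo, last)
        if hi > lo:
            total += hi - lo
            last = hi
    return total


def _consensus_breakpoints(blocks: list[SyntenyBlock], min_flank: int,
                           tolerance: int) -> dict[tuple[str, str],
                                                   list[int]]:
    """Per (genome, chromosome): rank positions where block-side endpoints
    from >= ``min_flank`` distinct partner chromosomes cluster (within
    ``tolerance`` ranks) on each flank -- ends on one side, starts on the
    other. At a fusion junction essentially every syntenic copy of either
    flank terminates, from as many partner chromosomes as the region has
    copies; the echo of a fission in the partner genome, by contrast, is
    supported only by the one or two broken copies."""
    # (genome, chrom) -> list of (position, which_end, partner_chrom)
    pts: dict[tuple[str, str], list[tuple[int, str, str]]] = defaultdict(list)
    for b in blocks:
        pts[(b.genome_a, b.chrom_a)] += [(b.lo_a, "start", b.chrom_b),
                                         (b.hi_a, "end", b.chrom_b)]
        pts[(b.genome_b, b.chrom_b)] += [(b.lo_b, "start", b.chrom_a),
                                         (b.hi_b, "end", b.chrom_a)]
    out: dict[tuple[str, str], list[int]] = {}
    for key, arr in pts.items():
        arr.sort()
        clusters: list[list[tuple[int, str, str]]] = [[arr[0]]]
        for x in arr[1:]:
            if x[0] - clusters[-1][-1][0] <= tolerance:
                clusters[-1].append(x)
            else:
                clusters.append([x])
        keep = []
        for c in clusters:
            enders = {p for _, which, p in c if which == "end"}
            starters = {p for _, which, p in c if which == "start"}
            if len(enders) >= min_flank and len(starters) >= min_flank:
                keep.append(int(c[len(c) // 2][0]))
        out[key] = keep
    return out


def _cut_anchor_list(anchors, cuts: list[int], key) -> list[list]:
    if not cuts:
        return [list(anchors)]
    cuts = sorted(cuts)
    bins: dict[int, list] = defaultdict(list)
    for a in anchors:
        k = key(a)
        b = 0
        while b < len(cuts) and k >= cuts[b]:
            b += 1
        bins[b].append(a)
    return [bins[b] for b in sorted(bins)]


def split_blocks_at_breakpoints(blocks: list[SyntenyBlock],
                                min_flank: int = 3, tolerance: int = 3,
                                min_anchors: int = 5) -> list[SyntenyBlock]:
    """Split blocks at consensus breakpoints on either side.

    A block genuinely spanning a fusion junction shared by both lineages
    would bridge two ancestral chromosomes; because the other syntenic
    copies all break there, the junction is recoverable as a high-support
    endpoint cluster and the spanning block is cut at it. ``min_flank``
    is the partner-chromosome support required of each flank -- one less
    than the expected region multiplicity (4 after two WGD rounds).
    """
    bp = _consensus_breakpoints(blocks, min_flank, tolerance)
    out: list[SyntenyBlock] = []
    for b in blocks:
        cuts_a = [p for p in bp.get((b.genome_a, b.chrom_a), ())
                  if b.lo_a + tolerance < p < b.hi_a - tolerance]
        pieces = _cut_anchor_list(b.anchors, cuts_a, lambda a: a.rank_a)
        final = []
        for piece in pieces:
            if not piece:
                continue
            lob = min(a.rank_b for a in piece)
            hib = max(a.rank_b for a in piece) + 1
            cuts_b = [p for p in bp.get((b.genome_b, b.chrom_b), ())
                      if lob + tolerance < p < hib - tolerance]
            final += _cut_anchor_list(piece, cuts_b, lambda a: a.rank_b)
        for piece in final:
            if len(piece) < min_anchors:
                continue
            bs = [a.rank_b for a in piece]
            out.append(SyntenyBlock(
                0, b.genome_a, b.genome_b, b.chrom_a,
                piece[0].rank_a, piece[-1].rank_a + 1,
                b.chrom_b, min(bs), max(bs) + 1, b.orientation, piece))
    out.sort(key=lambda blk: (blk.chrom_a, blk.lo_a, blk.chrom_b, blk.lo_b))
    for i, blk in enumerate(out):
        blk.block_id = i
    return out


def infer_ancestral_groups(blocks: list[SyntenyBlock],
                           min_component_genes: int = 30,
                           split_breakpoints: bool = True,
                           min_flank: int = 3,
                           tolerance: int = 3) -> list[AncestralGroup]:
    """Ancestral chromosome groups as connected components of the
    block-segment graph.

    Nodes are block sides; edges join (i) the two sides of every block and
    (ii) same-chromosome sides whose rank intervals overlap by >= 50% of
    the shorter interval (so a short block nested in a long one joins it).
    Components spanning >= ``min_component_genes`` (union of rank
    intervals) become groups, sorted by gene total, largest first.
    """
    if not blocks:
        raise ValueError("no blocks given")
    if split_breakpoints:
        blocks = split_blocks_at_breakpoints(blocks, min_flank, tolerance)
    G = nx.Graph()
    side_info: dict[tuple[int, str], tuple[str, str, int, int]] = {}
    by_chrom: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
    for b in blocks:
        for side, (g, c, lo, hi) in (("a", (b.genome_a, b.chrom_a, b.lo_a, b.hi_a)),
                                     ("b", (b.genome_b, b.chrom_b, b.lo_b, b.hi_b))):
            node = (b.block_id, side)
            side_info[node] = (g, c, lo, hi)
            by_chrom[(g, c)].append(node)
            G.add_node(node)
        G.add_edge((b.block_id, "a"), (b.block_id, "b"))
    for nodes in by_chrom.values():
        for i in range(len(nodes)):
            _, _, lo1, hi1 = side_info[nodes[i]]
            for j in range(i + 1, len(nodes)):
                _, _, lo2, hi2 = side_info[nodes[j]]
                ol = min(hi1, hi2) - max(lo1, lo2)
                if ol >= 0.5 * min(hi1 - lo1, hi2 - lo2):
                    G.add_edge(nodes[i], nodes[j])
    groups = []
    for comp in nx.connected_components(G):
        per_chrom: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for node in comp:
            g, c, lo, hi = side_info[node]
            per_chrom[(g, c)].append((lo, hi))
        total = sum(_union_length(v) for v in per_chrom.values())
        segments = sorted(
            (g, c, lo, hi) for (g, c), ivs in per_chrom.items()
            for lo, hi in ivs)
        if total >= min_component_genes:
            groups.append((total, segments))
    groups.sort(key=lambda t: (-t[0], t[1]))
    return [AncestralGroup(i, segs, tot)
            for i, (tot, segs) in enumerate(groups)]


def paint_chromosomes(genome: SimGenome | pd.DataFrame,
                      groups: list[AncestralGroup],
                      min_segment: int = 10) -> ChromosomePainting:
    """Assign each gene its ancestral group via segment membership, merge
    same-group runs, discard runs shorter than ``min_segment`` genes."""
    if isinstance(genome, SimGenome):
        table = genome.gene_table()
        genome_id = genome.genome_id
    else:
        table = genome
        genome_id = str(table.get("genome", pd.Series(["?"])).iloc[0])

    seg_by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for grp in groups:
        for g, c, lo, hi in grp.segments:
            if isinstance(genome, SimGenome) and g != genome_id:
                continue
            seg_by_chrom[c].append((lo, hi, grp.group_id))

    painted: dict[str, list[Segment]] = {}
    n_assigned = 0
    n_total = 0
    for chrom, sub in table.groupby("chrom", sort=True):
        ranks = sub["rank"].to_numpy()
        n_total += len(ranks)
        labels = []
        for r in ranks:
            cands = [gid for lo, hi, gid in seg_by_chrom.get(chrom, ())
                     if lo <= r < hi]
            labels.append(min(cands) if cands else -1)
        segs: list[Segment] = []
        run_start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[run_start]:
                gid = labels[run_start]
                if gid >= 0 and i - run_start >= min_segment:
                    segs.append(Segment(int(ranks[run_start]),
                                        int(ranks[i - 1]) + 1, gid))
                run_start = i
        painted[chrom] = segs
        n_assigned += sum(s.n_genes for s in segs)
    coverage = n_assigned / n_total if n_total else 0.0
    return ChromosomePainting(genome_id, painted, coverage)


def group_purity(groups: list[AncestralGroup], truth_ancestral_chrom,
                 gene_tables: dict[str, pd.DataFrame]) -> float:
    """Fraction of group-segment genes whose truth ancestral chromosome
    matches their group's majority label (majority-label oracle)."""
    votes: dict[int, Counter] = defaultdict(Counter)
    for grp in groups:
        for g, c, lo, hi in grp.segments:
            t = gene_tables[g]
            sub = t[(t["chrom"] == c) & (t["rank"] >= lo) & (t["rank"] < hi)]
            for aid in sub["ancestral_id"]:
                votes[grp.group_id][truth_ancestral_chrom(aid)] += 1
    good = total = 0
    for gid, cnt in votes.items():
        top = cnt.most_common(1)[0][1]
        good += top
        total += sum(cnt.values())
    return good / total if total else 0.0


# ---------------------------------------------------------------------------
# scenario inference from a painting
# ---------------------------------------------------------------------------

def count_junctions(painting: ChromosomePainting) -> Counter:
    """Multiset of distinct-group adjacencies (unordered group pairs)
    between neighbouring segments, over all chromosomes."""
    junctions: Counter = Counter()
    for segs in painting.segments.values():
        for s1, s2 in zip(segs, segs[1:]):
            if s1.group_id != s2.group_id:
                key = tuple(sorted((s1.group_id, s2.group_id)))
                junctions[key] += 1
    return junctions


def infer_event_scenario(painting: ChromosomePainting, n_wgd: int,
                         n_ancestral: int) -> KaryotypeScenario:
    """Greedy parsimony estimate of fusion/fission counts from a painting.

    Fusions are junctions between adjacent segments of different groups; a
    junction type duplicated across the genome is evidence of a fusion that
    predates the last WGD (the copy shares the internal breakpoint), so each
    pair of identical junction types is collapsed to one pre-WGD fusion.
    Fission counts then follow from the chromosome-count algebra, placing
    as many as possible in the earlier epoch (fewest total events), with the
    caveat that per-epoch placement is not identifiable in general.
    """
    if n_wgd not in (1, 2):
        raise ValueError("n_wgd must be 1 or 2")
    for segs in painting.segments.values():
        for s1, s2 in zip(segs, segs[1:]):
            if s2.lo < s1.hi:
                raise ValueError("inconsistent painting: overlapping segments")
    observed = painting.n_chromosomes
    expected = n_ancestral * 2 ** n_wgd
    junctions = count_junctions(painting)
    if n_wgd == 1:
        fusions = sum(junctions.values())
        fissions = max(0, observed - expected + fusions)
        return KaryotypeScenario(n_ancestral,
                                 [Epoch(True, fissions, fusions)])
    u_early = sum(c // 2 for c in junctions.values())
    u_late = sum(c % 2 for c in junctions.values())
    # chromosome-count algebra: 2*(f1 - u_early) + (f2 - u_late)
    #   = observed - expected, so 2*f1 + f2 = D below; maximizing f1
    # minimizes the total event count.
    D = observed - expected + 2 * u_early + u_late
    if D >= 0:
        f_early, f_late = D // 2, D % 2
    else:
        f_early = f_late = 0
    return KaryotypeScenario(n_ancestral, [Epoch(True, f_early, u_early),
                                           Epoch(True, f_late, u_late)])


# ---------------------------------------------------------------------------
# composition projection onto a third genome
# ---------------------------------------------------------------------------

def project_composition(painting: ChromosomePainting,
                        blocks: list[SyntenyBlock],
                        min_segment: int = 10) -> tuple[ChromosomePainting,
                                                        pd.DataFrame]:
    """Transfer ancestral-group labels across blocks onto the non-reference
    genome of ``blocks``; returns its painting plus per-chromosome
    per-group gene fractions (unassigned remainder allowed).
    """
    if not blocks:
        raise ValueError("no blocks given")
    if blocks[0].genome_a == painting.genome_id:
        ref = lambda b: (b.chrom_a, b.lo_a, b.hi_a)  # noqa: E731
        tgt = lambda b: (b.chrom_b, b.lo_b, b.hi_b)  # noqa: E731
    elif blocks[0].genome_b == painting.genome_id:
        ref = lambda b: (b.chrom_b, b.lo_b, b.hi_b)  # noqa: E731
        tgt = lambda b: (b.chrom_a, b.lo_a, b.hi_a)  # noqa: E731
    else:
        raise ValueError("blocks do not involve the painted genome")

    ref_side_is_a = blocks[0].genome_a == painting.genome_id

    def _label_at(chrom: str, rank: int) -> int:
        for s in painting.segments.get(chrom, ()):
            if s.lo <= rank < s.hi:
                return s.group_id
        return -1

    chrom_len: dict[str, int] = defaultdict(int)
    for b in blocks:
        c, _, hi = tgt(b)
        chrom_len[c] = max(chrom_len[c], hi)
    # anchor-level label transfer; conflicts resolved by block score,
    # then smaller group id
    assign: dict[str, dict[int, tuple[int, int]]] = defaultdict(dict)
    for b in blocks:
        tc = tgt(b)[0]
        for a in b.anchors:
            r_ref, r_tgt = (a.rank_a, a.rank_b) if ref_side_is_a \
                else (a.rank_b, a.rank_a)
            gid = _label_at(ref(b)[0], r_ref)
            if gid < 0:
                continue
            prev = assign[tc].get(r_tgt)
            if prev is None or b.score > prev[0] or \
                    (b.score == prev[0] and gid < prev[1]):
                assign[tc][r_tgt] = (b.score, gid)

    max_fill = 10  # unanchored ranks absorbed between same-label anchors
    painted: dict[str, list[Segment]] = {}
    frac_rows = []
    for chrom in sorted(chrom_len):
        n = chrom_len[chrom]
        ranked = sorted((r, gl[1]) for r, gl in assign[chrom].items())
        segs: list[Segment] = []
        for r, gid in ranked:
            if segs and segs[-1].group_id == gid and \
                    r - segs[-1].hi <= max_fill:
                segs[-1].hi = r + 1
            else:
                segs.append(Segment(r, r + 1, gid))
        segs = [s for s in segs if s.n_genes >= min_segment]
        painted[chrom] = segs
        per_group = Counter()
        for s in segs:
            per_group[s.group_id] += s.n_genes
        for gid, cnt in sorted(per_group.items()):
            frac_rows.append((chrom, gid, cnt / n))
    total = sum(chrom_len.values())
    covered = sum(s.n_genes for segs in painted.values() for s in segs)
    out = ChromosomePainting("projected", painted,
                             covered / total if total else 0.0)
    fractions = pd.DataFrame(frac_rows, columns=["chrom", "group_id",
                                                 "fraction"])
    return out, fractions
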
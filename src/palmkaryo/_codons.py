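"""Codon bookkeeping shared by the sequence simulator and the Ks estimator.

Site counting and pathway enumeration follow the classic pathway-counting
scheme: each codon position contributes synonymous "site fraction" equal to
the fraction of its three possible substitutions that preserve the amino
acid, substitutions creating a stop codon counting as nonsynonymous; between
two codons, synonymous/nonsynonymous differences are averaged over all
shortest mutational pathways that avoid stop-codon intermediates.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from Bio.Data import CodonTable

BASES = "TCAG"

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
CODON_TO_AA = dict(_table.forward_table)  # stops absent
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 codons


def is_synonymous(codon_from: str, codon_to: str) -> bool:
    """True when both codons are sense codons for the same amino acid."""
    if codon_to in STOP_CODONS or codon_from in STOP_CODONS:
        return False
    return CODON_TO_AA[codon_from] == CODON_TO_AA[codon_to]


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous sites of one codon (0..3): per position, the fraction of
    the three single-base changes that are synonymous."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site classification")
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                syn += 1
        s += syn / 3.0
    return s


def count_sites(seq: str) -> tuple[float, float]:
    """(S, N) totals for an in-frame coding sequence; S + N = length."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    S = 0.0
    for i in range(0, len(seq), 3):
        S += syn_sites(seq[i : i + 3])
    return S, len(seq) - S


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over all shortest
    mutational pathways that do not pass through a stop codon.

    If every pathway is blocked by a stop intermediate (possible for some
    two/three-fold changes), the average falls back to all pathways.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else valid).append((sd, nd))
    paths = valid or blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def random_sense_codons(rng, n: int) -> list[str]:
    """n codons drawn uniformly from the 61 sense codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def all_codon_pairs_check() -> None:  # pragma: no cover - debugging aid
    for a, b in product(SENSE_CODONS, repeat=2):
        pathway_counts(a, b)
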
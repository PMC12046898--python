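"""Telomere repeat scanning at chromosome ends.

Plant telomeres are tandem arrays of a conserved 7-bp unit (TTTAGGG on the
3'-running strand); a chromosome end is called telomeric when the terminal
window holds at least ``min_copies`` exact, non-overlapping copies of the
motif -- the reverse complement (CCCTAAA) at the 5' end, the motif itself
at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

PLANT_TELOMERE_MOTIF = "TTTAGGG"


@dataclass
class EndScan:
    end: str  # five_prime / three_prime
    motif: str
    copies: int
    present: bool


@dataclass
class TelomereScan:
    chrom: str
    five_prime: EndScan
    three_prime: EndScan

    @property
    def both_ends(self) -> bool:
        return self.five_prime.present and self.three_prime.present

    @property
    def total_copies(self) -> int:
        return self.five_prime.copies + self.three_prime.copies


def scan_telomeres(chrom_id: str, seq: str,
                   motif: str = PLANT_TELOMERE_MOTIF,
                   window: int = 10_000,
                   min_copies: int = 10) -> TelomereScan:
    """Count exact non-overlapping motif copies in the two terminal windows.

    Windows longer than half the sequence are truncated to half-length so
    the two ends never overlap.
    """
    if not seq:
        raise ValueError(f"empty sequence for {chrom_id!r}")
    seq = seq.upper()
    motif = motif.upper()
    w = min(window, len(seq) // 2)
    rc = str(Seq(motif).reverse_complement())
    n5 = seq[:w].count(rc)
    n3 = seq[len(seq) - w:].count(motif)
    return TelomereScan(
        chrom_id,
        EndScan("five_prime", rc, n5, n5 >= min_copies),
        EndScan("three_prime", motif, n3, n3 >= min_copies),
    )
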
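"""Scan chromosome ends for the plant telomere repeat.

Two constructed chromosomes: one with telomere arrays at both ends (the
reverse-complement CCCTAAA at the 5' end, TTTAGGG at the 3' end) and one
bare. A terminal end is called telomeric at >= 10 exact motif copies in
its 10 kb window.
"""

import numpy as np

from palmkaryo.chrom_features import scan_telomeres

rng = np.random.default_rng(0)
middle = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
chroms = {
    "chr1": "CCCTAAA" * 1312 + middle + "TTTAGGG" * 1247,
    "chr2": middle,
}

for cid, seq in chroms.items():
    scan = scan_telomeres(cid, seq, window=10_000)
    print(f"{cid}: 5' {scan.five_prime.copies} copies "
          f"(present={scan.five_prime.present}), "
          f"3' {scan.three_prime.copies} copies "
          f"(present={scan.three_prime.present}), "
          f"both_ends={scan.both_ends}, total={scan.total_copies}")
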
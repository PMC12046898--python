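"""Reading and writing the on-disk formats (GFF3, FASTA, TSV).

Internal gene coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive, so starts gain 1 on write and lose 1 on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score",
             "strand", "phase", "attributes"]


def write_gff3(gene_table: pd.DataFrame, path) -> Path:
    """Write a gene table (gene_id, chrom, start, end, strand, and optional
    ancestral_id / copy_label columns) as GFF3 gene features."""
    path = Path(path)
    extra_cols = [c for c in ("ancestral_id", "copy_label")
                  if c in gene_table.columns]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in gene_table.itertuples(index=False):
            attrs = [f"ID={row.gene_id}"]
            for c in extra_cols:
                attrs.append(f"{c}={getattr(row, c)}")
            fh.write("\t".join([
                str(row.chrom), "palmkaryo", "gene",
                str(int(row.start) + 1), str(int(row.end)), ".",
                row.strand, ".", ";".join(attrs),
            ]) + "\n")
    return path


def read_gff3(path) -> pd.DataFrame:
    """Read gene features back into the internal flat table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=_GFF_COLS, dtype={"seqid": str})
    df = df[df["type"] == "gene"].copy()
    attrs = df["attributes"].str.split(";").apply(
        lambda parts: dict(p.split("=", 1) for p in parts if "=" in p))
    out = pd.DataFrame({
        "gene_id": attrs.apply(lambda d: d["ID"]),
        "chrom": df["seqid"],
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "strand": df["strand"],
    })
    for c in ("ancestral_id", "copy_label"):
        if attrs.apply(lambda d: c in d).all():
            out[c] = attrs.apply(lambda d: d[c])
    out = out.sort_values(["chrom", "start"], kind="stable")
    out["rank"] = out.groupby("chrom", sort=False).cumcount()
    return out.reset_index(drop=True)


def write_fasta(seqs: dict[str, str], path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_pair_table(path) -> pd.DataFrame:
    """Two-column homolog-pair TSV (gene_a, gene_b); header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_a", "gene_b"]:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df.columns = ["gene_a", "gene_b"] + list(df.columns[2:])
    return df[["gene_a", "gene_b"]]


def read_matrix(path) -> pd.DataFrame:
    """Feature-by-sample TSV with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)
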
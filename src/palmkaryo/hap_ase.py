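"""TPM normalization, allele-specific expression calling, tissue
specificity, and differential-expression screening.

ASE on an allelic pair in one tissue requires, simultaneously and with
strict inequalities: the expressed-allele mean TPM above 1, |log2 fold
change| of the allele means above 1, and a two-sided Welch t-test on
log2(TPM + 1) replicate values below 0.05. Differential expression between
tissues uses the same test with Benjamini-Hochberg adjustment and the
|log2FC| > 1, adjusted p < 0.05 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EPS = 1e-9


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: (c/L) / sum(c/L) * 1e6 per sample column.

    All-zero samples stay all-zero. Missing or non-positive lengths raise
    with the gene named.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for gene {missing[0]!r}")
    L = lengths.loc[counts.index].astype(float)
    bad = L.index[L <= 0]
    if len(bad):
        raise ValueError(f"non-positive length for gene {bad[0]!r}")
    c = counts.to_numpy(dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    rate = c / L.to_numpy()[:, None]
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(denom > 0, rate / denom * 1e6, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def _welch_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values row-wise for 2-D arrays (rows =
    features, columns = replicates). Degenerate rows (zero variance in both
    groups): p = 1 when the means are equal, else p = 0."""
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degen = se2 == 0
    p[degen] = np.where(np.isclose(mx[degen], my[degen]), 1.0, 0.0)
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


@dataclass
class ASETest:
    pair_id: tuple[str, str]
    tissue: str
    tpm_h1: float
    tpm_h2: float
    log2fc: float
    p_value: float
    passes_tpm: bool
    passes_fc: bool
    passes_p: bool

    @property
    def is_ase(self) -> bool:
        return self.passes_tpm and self.passes_fc and self.passes_p


def _tissue_samples(samples: pd.DataFrame, tissue: str, hap: str) -> list[str]:
    sel = samples[(samples["tissue"] == tissue)
                  & (samples["haplotype"] == hap)]
    return list(sel["sample"])


def call_ase_table(pairs: pd.DataFrame, tpm: pd.DataFrame,
                   samples: pd.DataFrame, tissues=None,
                   tpm_rule: str = "either") -> pd.DataFrame:
    """ASE calls for every pair x tissue; vectorized over pairs.

    ``tpm_rule`` controls the TPM > 1 expression filter: 'either' (the
    larger allele mean), 'both', or 'mean'.
    """
    if tissues is None:
        tissues = list(dict.fromkeys(samples["tissue"]))
    g1 = pairs["gene_h1"].to_numpy()
    g2 = pairs["gene_h2"].to_numpy()
    out = []
    for tissue in tissues:
        s1 = _tissue_samples(samples, tissue, "H1")
        s2 = _tissue_samples(samples, tissue, "H2")
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError(f"tissue {tissue!r}: need >= 2 replicates "
                             "per haplotype")
        x1 = tpm.loc[g1, s1].to_numpy(dtype=float)
        x2 = tpm.loc[g2, s2].to_numpy(dtype=float)
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        log2fc = np.log2(m1 + EPS) - np.log2(m2 + EPS)
        if tpm_rule == "either":
            expressed = np.maximum(m1, m2) > 1.0
        elif tpm_rule == "both":
            expressed = np.minimum(m1, m2) > 1.0
        elif tpm_rule == "mean":
            expressed = (m1 + m2) / 2.0 > 1.0
        else:
            raise ValueError(f"unknown tpm_rule {tpm_rule!r}")
        p = _welch_rows(np.log2(x1 + 1.0), np.log2(x2 + 1.0))
        passes_fc = np.abs(log2fc) > 1.0
        passes_p = p < 0.05
        out.append(pd.DataFrame({
            "gene_h1": g1, "gene_h2": g2, "tissue": tissue,
            "tpm_h1": m1, "tpm_h2": m2, "log2fc": log2fc, "p_value": p,
            "passes_tpm": expressed, "passes_fc": passes_fc,
            "passes_p": passes_p,
            "is_ase": expressed & passes_fc & passes_p,
        }))
    return pd.concat(out, ignore_index=True)


def call_ase(pair: tuple[str, str], tpm: pd.DataFrame, samples: pd.DataFrame,
             tissue: str, tpm_rule: str = "either") -> ASETest:
    """ASE test for one allelic pair in one tissue."""
    df = call_ase_table(pd.DataFrame({"gene_h1": [pair[0]],
                                      "gene_h2": [pair[1]]}),
                        tpm, samples, [tissue], tpm_rule)
    r = df.iloc[0]
    return ASETest(pair, tissue, float(r.tpm_h1), float(r.tpm_h2),
                   float(r.log2fc), float(r.p_value), bool(r.passes_tpm),
                   bool(r.passes_fc), bool(r.passes_p))


def classify_specificity(ase_table: pd.DataFrame) -> pd.DataFrame:
    """Tissue-specificity classes for pairs with >= 1 ASE tissue:
    one_tissue (exactly 1), all (every tissue), multiple (otherwise)."""
    n_tissues = ase_table["tissue"].nunique()
    counts = (ase_table.groupby(["gene_h1", "gene_h2"])["is_ase"]
              .sum().astype(int))
    counts = counts[counts > 0]
    cat = np.where(counts == 1, "one_tissue",
                   np.where(counts == n_tissues, "all", "multiple"))
    return pd.DataFrame({"n_ase_tissues": counts,
                         "category": cat}).reset_index()


def screen_degs(tpm: pd.DataFrame, samples: pd.DataFrame,
                contrast: tuple[str, str], lfc_threshold: float = 1.0,
                alpha: float = 0.05) -> pd.DataFrame:
    """Differentially expressed genes between two tissues: Welch t-test on
    log2(TPM + 1) over all replicate samples of each tissue, BH-adjusted
    across genes; is_deg requires |log2FC| > 1 and adjusted p < 0.05
    (strict)."""
    t1, t2 = contrast
    for t in contrast:
        if not (samples["tissue"] == t).any():
            raise ValueError(f"tissue {t!r} absent from sample sheet")
    s1 = list(samples.loc[samples["tissue"] == t1, "sample"])
    s2 = list(samples.loc[samples["tissue"] == t2, "sample"])
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >= 2 replicates per tissue")
    x1 = tpm[s1].to_numpy(dtype=float)
    x2 = tpm[s2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = np.log2(m1 + EPS) - np.log2(m2 + EPS)
    p = _welch_rows(np.log2(x1 + 1.0), np.log2(x2 + 1.0))
    padj = multipletests(p, method="fdr_bh")[1]
    padj = np.maximum(padj, p)  # BH never reports below the raw p
    return pd.DataFrame({
        "gene": tpm.index, "contrast": f"{t1}_vs_{t2}",
        "log2fc": log2fc, "p_value": p, "padj": padj,
        "is_deg": (np.abs(log2fc) > lfc_threshold) & (padj < alpha),
    }).set_index("gene")
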
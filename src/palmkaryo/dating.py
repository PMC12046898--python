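"""Molecular dating: Ks estimation, Ks-peak detection, clock calibration,
and LTR insertion ages.

Ks/Ka use the pathway-counting estimator with Jukes-Cantor correction:
synonymous (S) and nonsynonymous (N) site totals are averaged over the two
sequences, observed differences are averaged over all shortest mutational
pathways per codon pair, and the raw proportions pS = Sd/S, pN = Nd/N are
corrected as K = -(3/4) ln(1 - (4/3) p). WGD peaks in a Ks distribution are
read from a Gaussian kernel density; an age for a peak follows from a
synonymous rate r as T = Ks / (2 r). LTR pairs are dated from their Kimura
two-parameter distance D as T = D / (2 mu), mu defaulting to 5.6e-10
substitutions/site/year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from ._codons import STOP_CODONS, count_sites, pathway_counts

DEFAULT_MU = 5.6e-10  # neutral substitutions / site / year


@dataclass
class CodonPairStats:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float


def _jc_correct(p: float, what: str) -> float:
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0.0:
        raise ValueError(f"{what} saturated (p = {p:.4f} >= 3/4)")
    return -0.75 * math.log(x)


def nei_gojobori_ks(cds_a: str, cds_b: str) -> CodonPairStats:
    """Pathway-counting Ks/Ka for an aligned, gap-free, in-frame CDS pair."""
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length")
    if len(cds_a) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at position {i}")
        sd, nd = pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    Sa, Na = count_sites(cds_a)
    Sb, Nb = count_sites(cds_b)
    S, N = (Sa + Sb) / 2.0, (Na + Nb) / 2.0
    pS, pN = Sd / S, Nd / N
    return CodonPairStats(S, N, Sd, Nd, pS, pN,
                          _jc_correct(pS, "Ks"), _jc_correct(pN, "Ka"))


@dataclass
class KsPeak:
    location: float
    height: float
    bandwidth: float


KS_GRID = np.arange(0.0, 3.0 + 1e-9, 0.005)
KS_MAX = 3.0  # saturation cutoff applied before peak detection


def detect_ks_peaks(ks_values, bandwidth: float | None = None,
                    min_values: int = 50) -> list[KsPeak]:
    """Peaks of a Gaussian KDE over the Ks sample on a fixed grid
    (0..3, step 0.005): local maxima above 10% of the global maximum,
    sorted by location. Bandwidth defaults to Silverman's rule; an explicit
    value is the kernel standard deviation in Ks units."""
    vals = np.asarray(ks_values, dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0) & (vals <= KS_MAX)]
    if len(vals) < min_values:
        raise ValueError(f"need >= {min_values} finite Ks values, "
                         f"got {len(vals)}")
    if bandwidth is None:
        kde = gaussian_kde(vals, bw_method="silverman")
    else:
        kde = gaussian_kde(vals, bw_method=bandwidth / vals.std(ddof=1))
    dens = kde(KS_GRID)
    bw_used = float(np.sqrt(kde.covariance[0, 0]))
    floor = 0.1 * dens.max()
    peaks = []
    for i in range(1, len(KS_GRID) - 1):
        if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1] \
                and dens[i] >= floor:
            peaks.append(KsPeak(float(KS_GRID[i]), float(dens[i]), bw_used))
    peaks.sort(key=lambda p: p.location)
    return peaks


@dataclass
class MolecularClock:
    r: float  # synonymous substitutions / site / year (Ks dating)
    mu: float = DEFAULT_MU  # neutral rate (LTR dating)


def calibrate_rate(ks_peak: float, age_years: float) -> float:
    """Synonymous rate from a Ks peak of known age: r = Ks / (2 T)."""
    if ks_peak <= 0 or age_years <= 0:
        raise ValueError("ks_peak and age must be positive")
    return ks_peak / (2.0 * age_years)


def date_event(ks_peak: float, clock: MolecularClock | float) -> float:
    """Age of a Ks peak in years: T = Ks / (2 r)."""
    r = clock.r if isinstance(clock, MolecularClock) else float(clock)
    if ks_peak < 0 or r <= 0:
        raise ValueError("ks_peak must be >= 0 and r > 0")
    return ks_peak / (2.0 * r)


_PURINES = frozenset("AG")


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Kimura two-parameter distance: (P, Q, D) with P the transition and
    Q the transversion proportion over unambiguous ungapped sites and
    D = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    valid = frozenset("ACGT")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in valid or b not in valid:
            continue
        n += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"K2P saturated (P = {P:.3f}, Q = {Q:.3f})")
    return P, Q, -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class LTRRecord:
    element_id: str
    P: float
    Q: float
    D: float
    T_years: float


def ltr_insertion_age(D: float, mu: float = DEFAULT_MU) -> float:
    """Insertion age of an LTR element from its 5'/3' LTR divergence:
    T = D / (2 mu)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return D / (2.0 * mu)


def date_ltr_elements(pairs, mu: float = DEFAULT_MU) -> list[LTRRecord]:
    """K2P-date a collection of (element_id, ltr5, ltr3) triples."""
    out = []
    for element_id, ltr5, ltr3 in pairs:
        P, Q, D = k2p_distance(ltr5, ltr3)
        out.append(LTRRecord(element_id, P, Q, D, ltr_insertion_age(D, mu)))
    return out
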
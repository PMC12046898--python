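# Methods

This note documents the models behind each module, the defaults and why
they were chosen, the numerical conventions, and what the simulator does
and does not emulate. Problem sizes quoted are the ones the test suite and
acceptance script actually run.

## The genome simulator

A genome is an ordered list of chromosomes, each an ordered list of genes;
gene coordinates are internal bookkeeping (0-based half-open, re-laid-out
after every rearrangement), while the unit of all downstream analysis is
the gene *rank* — the dense ordinal position on its chromosome. Every gene
carries a stable `ancestral_id` (the founding gene of its family), which
defines truth homology under all events.

Events and their semantics:

* **WGD** duplicates every chromosome; copies get fresh gene/chromosome ids
  and extended copy labels.
* **Fusion** concatenates two chromosomes; the joined end is random by
  default (orientation `+` appends, `-` appends reversed with strands
  flipped), as real fusions join either chromosome end.
* **Fission** splits a chromosome before a gene rank.
* **Inversion** reverses gene order and strands on a rank interval.
* **Loss** (fractionation) drops each gene copy independently with
  probability 1 − retention, never deleting a genome's last copy of an
  ancestral gene, so truth homology stays connected.

The *standard simulation* is the package's reference condition: a
6-chromosome ancestor with 200 genes per chromosome; lineage A follows the
betel-palm history (WGD; 2 fissions + 5 fusions; WGD; 1 fission + 3
fusions ⇒ 16 chromosomes), lineage B a second monocot-like history with
the same two WGDs but its own rearrangements (⇒ 20 chromosomes); 3
inversions per epoch per lineage; retention 0.8 after each WGD. The
partner lineage's real history is unknown; its scenario is a free choice
made once, with fusion/fission picks drawn from the scenario seed so the
two lineages' junctions are independent. All generators are
bit-reproducible given a seed.

**Sequence pairs.** Codon pairs evolve from a random stop-free sequence by
proposing uniform single-base changes and accepting only synonymous ones;
the number of accepted events is Poisson with mean `ks_target × S`
(S = synonymous sites of the ancestor, pathway-counting convention), split
binomially between the two descendants. The logged truth is events divided
by the mean synonymous-site count of the two final sequences. LTR pairs
start identical and each copy accumulates Poisson(mu · T · length) uniform
substitutions, so the expected pairwise divergence is 2 mu T.

**Expression.** Each allelic pair has a gamma(1.5, 40) baseline on the TPM
scale, a per-tissue log-normal multiplier (log2 sd 0.4 by default),
optional planted tissue-differential genes, a planted allele fold change
on an `ase_fraction` of pairs (direction random), log-normal replicate
noise (log2 sd 0.1), and Poisson counts scaled to a 5e6 library with 10%
log-normal depth jitter. Samples are (tissue × replicate × haplotype);
each haplotype's genes are counted in that haplotype's sample columns.

**Metabolome.** Linked metabolites are built directly on the standardized
log2 expression profile z of a randomly chosen panel gene:
`log2 m = ±(r·z) + sqrt(1−r²)·ε`, giving planted |Pearson r| ≈ `target_r`
on the log scale with a random sign; unlinked metabolites are independent
log-normal noise. Metabolites get one of eight class labels (alkaloid,
flavonoid, …) for node annotation.

What the simulator does **not** emulate: nucleotide-level chromosome
sequences (no breakpoint sequences, no repeats), read-level data,
overdispersed negative-binomial count noise, isoform structure, tandem
duplications, gene conversion between WGD copies, or metabolite
identification noise. Tests passing on it show the *inference machinery*
is correct under its stated model, not that real data meet that model.

## Synteny

Anchors are homolog pairs in rank space. Chaining is per chromosome pair:
the highest-score chain (score = anchor count) under strict monotonicity
in both rank coordinates (increasing, or decreasing in the partner for
inverted blocks) with both rank gaps ≤ `max_gap` (default 25) is extracted,
its anchors removed, and the process repeated until the best chain falls
below `min_block_anchors` (default 5). Strict monotonicity in both
coordinates is what prevents degenerate vertical/horizontal chains from
tandem-duplicate anchors; a global collapse to one anchor per rank would
instead delete the extra WGD copies and destroy the multiplicity signal.
Greedy best-first extraction is the field's standard; it equals the exact
set-packing optimum on uniform random small instances (verified against a
brute-force oracle on 1000 instances of ≤ 12 anchors), but contrived
instances exist where the best single chain straddles two parallel runs
and its removal fragments both — a known property of this algorithm
family, inherited here.

**Multiplicity** counts, for non-overlapping windows of `window` gene
ranks (default 20), the distinct blocks *fully containing* the window;
containment rather than overlap makes the count a local copy number
(fragments of heavily fractionated copies stop registering). The mode over
covered windows is reported per genome. At retention 0.8 the standard
simulation gives 4:4; erosion below 4 appears only under much heavier
fractionation (around retention 0.1 in extra loss), because blocks
tolerate large anchor gaps.

**Allelic pairs.** Between two haplotypes, blocks are accepted
best-score-first subject to non-overlap on both haplotypes (one block per
region); their anchors become one-to-one pairs. CDS identity is computed
by global alignment (match +1, mismatch −1, gap −2) as identical columns
over alignment length; classes are identical (100%), similar
(≥ `similar_threshold`, default 80%), diverged. The 80% boundary is a
convention — only the 100% boundary is principled.

## Karyotype

**Group inference** formalizes the manual reading of a dotplot: nodes are
block sides; edges join the two sides of each block, and same-chromosome
sides whose rank intervals overlap by ≥ 50% of the shorter interval (so a
nested short block joins its host region). Connected components with
≥ `min_component_genes` (default 30, union of rank intervals) are the
ancestral groups. Two practical points matter:

1. *Use cross-genome blocks.* Within-genome self-synteny spans every
   fusion junction fixed before that genome's last WGD (the duplicated
   copies are collinear across the junction), which would merge the two
   flanking groups into one component. The partner lineage, whose
   junctions are elsewhere, breaks blocks at exactly those points.
2. *Consensus breakpoints.* When both lineages happen to share a collinear
   junction, a genuine spanning block still bridges two groups. Before
   component building, block sides are therefore split wherever block-side
   endpoints from ≥ `min_flank` distinct partner chromosomes cluster
   (within `tolerance` = 3 ranks) on each flank — ends on one side, starts
   on the other. At a true junction essentially every syntenic copy of
   either flank terminates (support ≈ multiplicity − 1, hence the default
   `min_flank` = 3 for a two-WGD comparison); the echo of a single fission
   in the partner genome musters at most the one or two broken copies and
   is ignored, which keeps genuine regions from being split apart.

On the standard simulation this recovers exactly 6 groups in 8 of 10
seeds (failures are one residual merge or one split, majority 6), with
group-to-truth purity 1.00 and painting coverage ≥ 0.99 on the default
seed.

**Painting** assigns each gene the group of the segment containing its
rank (ties to the smaller group id), merges same-group runs and drops runs
shorter than `min_segment` (default 10 genes).

**Event accounting** is exact arithmetic: WGD doubles the count, each
fission adds one, each fusion removes one, in epoch order, with every
intermediate required ≥ 1.

**Scenario inference** estimates event counts back from a painting.
Fusions are junctions between adjacent segments of different groups; a
junction *type* (unordered group pair) occurring twice is evidence of one
fusion predating the last WGD (its copy shares the breakpoint), so pairs
collapse to single early fusions. Fissions follow from the count algebra
`2(f1 − u1) + (f2 − u2) = observed − n_ancestral·2^n_wgd`, resolved by
parsimony (fewest events, i.e. placing fissions early). Per-epoch
placement is fundamentally ambiguous; only totals should be interpreted,
and same-group fusions are invisible to junction counting. On a
constructed scenario with distinct junction types and retention 0.9 the
true totals (8 fusions, 3 fissions) are recovered exactly; on random
scenarios with colliding junction types the estimate is a lower bound.

**Composition projection** transfers group labels across blocks at anchor
resolution (conflicts resolved by block score), merges same-label runs
(absorbing ≤ 10 unanchored ranks), and reports per-chromosome group
fractions; projecting a painting through identity self-blocks reproduces
it exactly.

## Dating

`nei_gojobori_ks` classifies sites by the fraction of single-base changes
that are synonymous (changes to stops count as nonsynonymous), averages
synonymous/nonsynonymous differences over all shortest mutational pathways
that avoid stop intermediates (falling back to all pathways when every one
is blocked), averages site totals over the two sequences, and applies the
Jukes–Cantor correction to both pS and pN. It agrees to machine precision
with an independent library implementation of the same estimator. Under
the simulator's synonymous-acceptance process the estimator is essentially
unbiased to Ks ≈ 0.3 and increasingly inflated beyond (signed bias at
10,000 codons: +0.001, +0.008, +0.022, +0.116 at Ks 0.1/0.3/0.5/0.9;
mean over that grid +0.037). The inflation is structural: the JC inversion
assumes every synonymous site exchanges among 4 states, while two-fold
degenerate sites toggle between 2, so the correction over-corrects as
divergence grows. Saturation (pS ≥ 3/4) raises an error.

Peak detection evaluates a Gaussian KDE (Silverman bandwidth by default;
an explicit bandwidth is the kernel sd in Ks units) on the fixed grid 0–3
in steps of 0.005 after discarding Ks > 3, and reports local maxima above
10% of the global maximum, sorted by location. Clock arithmetic is exact:
`r = Ks/(2T)` and `T = Ks/(2r)`, so calibrating on (0.9, 80.34 Myr) dates
Ks 0.3 at 26.78 Myr identically. K2P excludes ambiguous/gapped sites
pairwise and errors on saturation. The default LTR rate `mu = 5.6e-10`
/site/year is the conventional input used here verbatim; note that a rate
calibrated from the Ks clock above would be ten times larger — both are
explicit arguments, and ages scale as 1/mu.

## Expression

TPM is `(c/L) / Σ(c/L) × 1e6` per sample; all-zero samples stay zero.
ASE testing uses replicate means per allele, `log2((m1+ε)/(m2+ε))` with
ε = 1e-9, a two-sided Welch t-test on log2(TPM+1) replicates, and strict
thresholds (TPM > 1 for the larger allele mean by default — `tpm_rule`
also offers `both` and `mean`; |log2FC| > 1; p < 0.05). Zero-variance
degenerate cases: p = 1 when means are equal, 0 otherwise. Exact-boundary
cases (fold change exactly 2) are excluded by strictness. DEG screening is
the same test between tissues plus Benjamini–Hochberg across genes; it is
a deliberate, documented replicate-level test on normalized values with
the study's thresholds, not a count-model GLM, and should be run within
one haplotype's samples (a gene quantified only in its own haplotype's
columns has structural zeros elsewhere). Operating characteristics on the
generator (200 pairs, 12 tissues, 3 replicates, noise sd 0.1, 20 seeds):
sensitivity ≥ 0.9 and FDR ≤ 0.1 on planted 4-fold allelic effects;
pair-tissue null call rate ≤ 0.07. The planted-DEG check (50 of 2,000
genes at 8-fold) runs with between-tissue variation switched off, since
the generator's own tissue effects are real differences, not false
positives.

## Metabolites and networks

PLS-DA runs NIPALS on autoscaled log2(x+1) intensities against the
centered one-hot group matrix, default 2 components (capped by rank);
zero-variance variables are excluded with a warning. Per component,
explained-Y sum of squares is `(t·t)(q·q)`, and
`VIP_j = sqrt(p Σ_a SSY_a w_aj² / Σ_a SSY_a)` with unit-norm weights, so
mean VIP² = 1 identically. A model explaining no Y variance yields VIP = 0
with a warning rather than an error (no variable is important). NIPALS
weights and scores match a direct eigen-decomposition of X′YY′X and an
established PLS implementation up to component sign.

DAM screening: fold change of raw group means (ε = 1e-9) with VIP from a
two-group model; strict thresholds (FC > 2 or < 0.5, VIP > 1); ≥ 3
samples per group required.

The network correlates log2(x+1) values (Pearson by default, Spearman by
flag) over matched sample columns (≥ 3 required; single-digit n makes
individual correlations unstable and is the regime where the |r| > 0.8
filter does most of the work). Per metabolite: rank genes by |r|
descending (ties by gene id), truncate to `top_k` = 5, then filter to
|r| > 0.8; the alternative filter-then-truncate order is exposed because
the rule's wording admits both. Metabolites with fewer than five genes
above threshold keep fewer edges. At n = 9 samples the chance of
|r| > 0.8 for an unrelated pair is ≈ 1%, so network precision is governed
by the size of the candidate gene panel: with a screened panel of a couple
of genes, ≥ 90% of planted links (ρ = 0.95) are recovered at ≥ 90%
precision (pooled over 20 seeds); with hundreds of candidate genes at this
n, chance edges dominate any threshold rule of this form.

## Telomeres

Exact, non-overlapping counts of the 7-bp plant motif (which cannot
overlap itself): the reverse complement CCCTAAA in the first `window` bp
(default 10 kb), the motif itself in the last; windows shrink to half the
sequence for short records; an end is telomeric at ≥ `min_copies`
(default 10). Reverse-complementing a chromosome exactly swaps the two
ends' counts. The motif and thresholds are conventions, configurable.

## Problem sizes

The default test-and-acceptance scale: 6 × 200-gene ancestor
(≈ 3,100–3,200 genes per evolved genome, ≈ 8,200 cross-genome homolog
pairs), 10 seeds for the group-recovery majority; 10,000-codon pairs × 20
seeds × 4 grid points for estimator bias; 1000 instances for the chaining
oracle; 200 pairs × 12 tissues × 3 replicates × 20 seeds for ASE operating
characteristics; 100 metabolites × 9 samples × 20 seeds for network
recovery. The full suite runs in a few minutes on one CPU.

## Known limitations

* Greedy chaining can be suboptimal under block contention (above).
* Group inference assumes the two lineages' rearrangements are largely
  independent; shared collinear junctions beyond what consensus
  breakpoints can resolve merge groups (observed in ~2/10 seeds).
* Event-count inference sees only distinct-group junctions: same-group
  fusions and junction-type collisions bias counts low, and per-epoch
  placement is reported by parsimony convention, not evidence.
* Ks above ≈ 0.5 is increasingly overestimated under this substitution
  process; peak locations inherit that shift.
* The ASE/DEG tests are normalized-value t-tests, not count models; at 2–3
  replicates their power profile differs from GLM-based tools.
* All performance numbers are properties of the simulator's model of the
  data, not of any real dataset.
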
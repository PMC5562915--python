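# Methods

## Scope and data model

The pipeline operates on gene × tissue FPKM matrices from two
independent consortia (a primary and a validation dataset over the
same ~30 tissues), a secretory-pathway annotation (gene → functional
module, subsystem, gene family), and per-protein PTM features in
UniProt-dialect GFF (column 1 the accession, column 3 the feature
type, column 9 a `Note=` text). FPKM > 1 defines detection. Duplicate
gene rows collapse by per-tissue maximum — conservative for presence
calls. Genes present in expression but absent from the GFF keep a
zero-count PTM record flagged `unannotated` rather than being dropped,
since the load estimator sums over expressed secretome genes
regardless of annotation completeness. One `Disulfide bond` feature
counts one site (bonds, not half-cystines); counting bonded residues
instead would scale DS_e by a uniform log10(2) and change no
correlation or regression conclusion. The GFF dialect has no field for
an unconventional-secretion score or localization, so both are
consumed from an optional sidecar TSV merged into the PTM records.

## Category classification

The six rules partition every profile; several overlap, so order
matters. Rules are evaluated specificity-first — NotDetected,
TissueEnriched, GroupEnriched, TissueEnhanced, ExpressedInAll, Mixed —
matching the convention that enrichment categories dominate ubiquity
(the published counts place ~75% of pathway genes in *expressed in
all* only after enriched genes are removed). Fold thresholds are
inclusive (≥ 5); detection is strict (FPKM > 1, so a tissue at exactly
1 is neither "detected" for rule 4 nor "< 1" for rule 1). A
TissueEnriched call requires a unique top tissue; exact ties fall
through to the group/enhanced rules. Group-enriched groups are greedy
prefixes of the descending-FPKM ordering, sizes 2–7, each prefix's
mean tested against 5× the maximum of the remaining tissues —
exhaustive subset search is exponential and the prefix family contains
every group the rule could accept with distinct values.

## Extreme-gene detection

The unit of testing is the gene's *family share* across tissues: the
family's total output may legitimately vary between tissues, and the
share cancels both that variation and any per-tissue library-size
scale (detection is invariant to multiplying a tissue's column by a
constant). Shares are computed on raw FPKM — a log transform would
destroy the additivity that makes the share meaningful.

The Grubbs statistic G = max|x − x̄|/s (s with n−1 denominator) is
bounded by (n−1)/√n. The two-sided p-value uses the classical
t-inversion p = min(1, 2n·P(T_{n−2} ≥ t)) with
t² = n(n−2)G²/((n−1)² − nG²). This is a union bound: exact in the tail
(verified against a 10⁵-draw Monte-Carlo oracle to ≤ 1e−2 absolute for
p ≤ 0.2 at n ∈ {5, 10, 30}, and to ~1e−13 against an independent
numerical inversion of the critical-value formula), but conservative
mid-range — at n = 30 it overstates p ≈ 0.45 as 0.5, and it clamps to
1 well before G reaches 0. Consequently null p-values are *not*
uniform even for exact normal samples; calibration claims are made for
the decision-relevant tail only.

Only above-mean outliers with p < alpha (default 0.05, raw — no
multiple-testing correction by default, with a Benjamini–Hochberg mode
available) become extreme calls; below-mean outliers are reported
separately. Family shares are ratios of (log-normally distributed)
expression values, so the normality assumption fails and per-dataset
calls run several-fold above the nominal alpha. This is intrinsic to
the method; the two-dataset consensus — a call is validated only when
the identical (gene, tissue) pair recurs in the independent dataset —
is the operational false-positive control, and the validated rate on
spike-free synthetic data stays well under alpha × family size.
Iterative masking (re-testing a gene after removing its called tissue)
is off by default, depth 2 when enabled. Fold changes are reported on
raw FPKM against the median of the other tissues.

## Correlation structure

Tissue–tissue Pearson correlations are computed over log10(FPKM+1)
profiles (a raw-scale flag exists); zero-variance tissues yield
missing entries rather than silent zeros. Clustering is agglomerative
with average linkage on d = 1 − ρ — robust for correlation matrices
and free of the chaining artifacts single linkage shows here — and the
flat 2-group split (`fcluster`, maxclust) is what the low-correlation
tissue analysis consumes. The permutation test's statistic is the
median ρ over (in-group, out-group) tissue pairs; its null redraws
gene sets of equal size uniformly from all genes in the matrix,
because the scientific question is whether *this* gene set correlates
less than a typical gene set of the same size, not whether tissue
labels are exchangeable. p-values use the add-one rule and can never
be 0. Family correlation profiles require ≥ 3 members (Pearson over
two points is ±1 by construction) and offer a reference-tissue mode
and an all-pairs mode.

## Disulfide load and enzyme association

The secretome analysis set is the signal-peptide-bearing proteins;
proteins without a signal peptide but with an unconventional-secretion
score > 0.6 are tracked and excluded (their inclusion could only
increase DS_e, never decrease it — asserted as an invariant). DS_e(t)
= log10(Σ fpkm_{i,t}·ds_i); a tissue with zero weighted sum is
undefined and excluded from regressions. An optional restriction
limits the set to tissue-specific categories. Enzyme association is
ordinary least squares of FPKM on DS_e across tissues with the Pearson
t-test p-value and a t-based 95% CI on the slope; it requires ≥ 3
defined loads and a non-constant DS_e. PTM count columns are
discretised against the terciles of their nonzero values with a
separate "none" bin for zeros.

## Synthetic data generator

The generator emulates a two-consortium FPKM meta-analysis on the
natural-log scale. Gene g draws a latent log-mean; members of a gene
family scatter (sd 0.5) around a shared family mean (family means and
independent genes: sd 1 around loc 1) — co-regulated paralogs with an
order-of-magnitude between-family spread. Baseline log-FPKM is the
latent mean plus i.i.d. N(0, 0.2²) per tissue: exchangeable across
tissues, the null the Grubbs scan assumes, and deliberately small —
the pathway is housekeeping-like. Both datasets share this structure;
each adds its own N(0, 0.4²) log-noise, so the cross-tissue
fluctuations a single dataset shows are mostly dataset-specific
measurement artifacts, which is exactly what the consensus step is
meant to remove. Spikes multiply the target cell by the planted fold
(default 10) in both datasets. Two independent seed streams separate
structure from noise; the plan seed fully determines every output,
byte for byte.

The planted low-correlation tissue group redraws 60% of the latent
log-mean variance group-specifically for the annotated pathway genes,
giving between-group profile correlations near 0.55 against
within-block values near 0.85 — the contrast the tissue clustering and
permutation test must recover. The matrix additionally carries a large
pool of unannotated "transcriptome" genes (default 800) with plain
structure: they are the permutation test's null pool, mirroring a
pathway that is a small fraction of the measured transcriptome.

Secretome clients receive a per-tissue log-scale factor (sd 0.5) —
tissues genuinely differ in secretory output — which is what spreads
DS_e across tissues (range ≈ 1 in log10 units). Disulfide counts are
gamma-Poisson (mean 6, dispersion 1): overdispersed nonnegative
integers with a wide dynamic range. The enzyme family's FPKM per
tissue is slope·DS_e(t) + N(0, sd) with the planted slope 3 and, by
default, sd equal to 10% of the signal range slope·(max − min DS_e),
computed per dataset from its own emitted secretome.

Category-plant vectors are constructed to satisfy each rule with a
≥ 10% margin and carry a small log-jitter (sd 0.05) instead of the
full replicate noise, so the planted category survives in both emitted
datasets; the TissueEnhanced construction uses seven near-equal
runner-up tissues so that no 2–7 prefix passes the group rule while
the top tissue clears 5× the overall mean.

## What the synthetic tests do and do not show

Passing tests demonstrate correct implementations and sensible
operating characteristics under the generator's assumptions:
log-normal marginals, tissue exchangeability off the planted
structure, family co-regulation, and measurement noise independent
between datasets. Real consortium data add features the generator
omits: correlated tissues (brain sub-regions), shared donors within a
dataset, zero inflation at low expression, annotation errors, and
families whose members differ in expression by far more than the
within-family sd used here. Two consequences observed on the
generator carry over qualitatively to real data: spikes on a family
member that already dominates its family total are structurally hard
for the share-based test (the share saturates near 1), and tissues
with genuinely divergent expression (the low-correlation group)
produce extra extreme calls — in the published analysis, too, the
outlier tissues carry the largest extreme-gene sets.

## Problem sizes and numerical choices

Operating characteristics are estimated over 100 seeded studies: the
spike-recovery configuration uses 20 tissues and 10 families of sizes
4–12 with 15 ten-fold spikes; correlation and load analyses use the
default 30-tissue plan (~1400 genes). The permutation test uses 199
permutations in batch estimates and 999 in the single worked analysis.
These sizes give stable estimates (binomial se ≤ 3 points at 100
seeds) at a few seconds per batch. Grubbs p-values are floored at the
smallest positive double; fold changes against a zero median report
infinity; tied maximal deviations break to the lowest index, logged.
Tissue names are harmonised case-insensitively with an optional alias
map; families below 3 usable members are skipped and logged.

## Known limitations

The Grubbs p-value is a union bound — mid-range p-values are
conservative and should not be interpreted beyond the tail. The
share-based scan cannot flag a spike in a member that already carries
most of its family's expression. The greedy-prefix group-enriched
search can differ from an exhaustive subset search on profiles with
ties. DS_e weights annotation-derived disulfide counts, which include
computationally predicted sites; the estimator is a demand proxy, not
a measurement. Unique-gene versus (gene, tissue)-pair counts of
extreme genes are both reported, since shared genes make them differ.
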
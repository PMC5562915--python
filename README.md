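# secpath

Tissue-specific tuning of the human protein secretory pathway, as a
reusable and fully tested analysis pipeline.

## The problem

The secretory pathway — the ER→Golgi→membrane machinery that folds,
modifies and traffics secreted and membrane proteins — is expressed
almost everywhere: most of its ~575 core components fall in the
*expressed in all tissues* category. Yet the proteins it processes (the
secretome) are strongly tissue specific, and so is their demand for
post-translational processing (disulfide bonds, N-/O-glycosylation,
GPI anchors). This package implements a meta-analysis over two
replicate gene × tissue FPKM datasets that asks where, despite its
housekeeping character, the pathway's expression is fine-tuned per
tissue — and whether that tuning tracks the processing load.

It is aimed at computational biologists who want to run the analysis
on their own expression matrices (e.g. GTEx- and HPA-style FPKM
tables) or to study its operating characteristics on synthetic data
with planted ground truth.

## The statistics at the core

**Six-category tissue-specificity classification** of an FPKM vector
x over tissues (detection threshold FPKM > 1, fold threshold 5,
inclusive): *not detected* (all x < 1), *tissue enriched* (unique top
tissue ≥ 5× every other), *group enriched* (a group of 2–7 tissues with
mean ≥ 5× the max of the rest), *tissue enhanced* (top ≥ 5× the overall
mean), *expressed in all* (all x > 1), *mixed* (the remainder) —
evaluated specificity-first so enrichment dominates ubiquity.

**Extreme genes.** Within each gene family the member g is summarised
by its family share per tissue t,

    s_{g,t} = fpkm_{g,t} / Σ_{g'∈family} fpkm_{g',t},

which cancels family-total and library-size variation. The Grubbs
statistic on the share vector across tissues,

    G = max_t |s_{g,t} − s̄_g| / sd(s_g),

with the two-sided p-value from t² = n(n−2)G² / ((n−1)² − nG²),
p = min(1, 2n·P(T_{n−2} ≥ t)), flags outliers; above-mean outliers with
p < 0.05 become (gene, tissue) *extreme calls*, and a call is
*validated* when the identical pair recurs in the second, independent
dataset (shares are non-normal, so raw calls run anticonservative —
the consensus step is what controls false positives).

**Correlation structure.** Pearson correlation between tissues over
log10(FPKM+1) profiles of a gene set; average-linkage clustering on
1 − ρ with a 2-group split; and a permutation test for whether a tissue
group correlates unusually weakly with the rest for that gene set
(null: gene sets of equal size redrawn from the whole matrix).

**Disulfide load.** Per tissue, the disulfide enrichment estimator
over the secretome (signal-peptide proteins; unconventional-secretion
candidates with score > 0.6 excluded):

    DS_e(t) = log10( Σ_i fpkm_{i,t} · ds_i ),

with ds_i the protein's annotated disulfide-bond count. Each
disulfide-isomerase-family member's FPKM is regressed on DS_e across
tissues (OLS; Pearson t-test p-values; 95% CI on the slope).

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic two-consortium dataset with planted ground truth
(30 tissues, 11 gene families, 15 ten-fold spikes, an 8-tissue
low-correlation group, and a PDI-like enzyme family tied to the
disulfide load with slope 3):

```bash
python analysis/01_simulate.py
python analysis/02_classify_categories.py
python analysis/03_correlation_structure.py
python analysis/04_extreme_genes.py
python analysis/05_disulfide_load.py
```

The classification step recovers all 60 planted category genes
(`planted-category accuracy: 60/60`). The correlation step prints

```
planted low-correlation group: ['T01', ..., 'T08']
2-group split recovers it: True
median between-group rho = 0.530, permutation p = 0.0010
```

— the planted group separates cleanly and its between-group median ρ
is far below what random gene sets of the same size produce. The
extreme-gene step reports `validated calls: 15 (15 unique genes)` with
12 of the 15 planted spikes recovered on this seed (the three misses
sit in the low-correlation tissues, where the exchangeability the test
leans on is deliberately broken), and the disulfide step ends with

```
planted enzyme slope: 3.0
  PDI_01: slope 3.166 (5.5% off), r 0.925, p 2.71e-13
  ...
```

The same stages are available as a CLI for external data
(`secpath classify|correlate|families|extreme|ptm-load|network|all`);
every run writes a provenance record alongside its outputs.

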
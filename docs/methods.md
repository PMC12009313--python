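# Methods

`exqtl` implements a multi-level integration of genetic and transcriptomic
evidence for cross-disorder psychiatric cohorts: exon-resolution
differential expression and cis-eQTL mapping, polygenic eQT-Scores, a
common/rare core-gene intersection, and downstream enrichment analyses.
Because the cohorts this design targets (postmortem cortex with controlled
genotypes) are not freely redistributable, every stage is validated on a
synthetic cohort generator with known ground truth. This note documents
the models, the defaults and why they were chosen, the numerical
conventions, and what passing tests do and do not establish.

## The shared linear-model engine

Every association stage fits ordinary least squares per expression feature:

    y_j = b0 + b1 * x + C gamma + e,    e ~ N(0, s^2 I)

where `x` is the predictor of interest — a 0/1 diagnosis indicator
(differential expression), an additive SNP dosage (cis-eQTL), or a
per-sample polygenic risk score (eQT-Score) — and `C` contains the
postmortem-brain covariates: age, sex, pH, postmortem interval, RIN and
RIN², suicide status, cause of death (3-level categorical, dummy-coded
against the "natural" reference), four genotype-derived ancestry
dimensions and one surrogate variable taken as given. Inference for `b1`
uses the Student t distribution with `n - p` residual degrees of freedom.
The matrix form shares the normal equations across features, so a scan of
thousands of exons is a single solve plus matrix products; it is exactly
equal to per-feature fits (tested against an independent OLS
implementation to 1e-8). Moderated/empirical-Bayes variance shrinkage is
deliberately not used: plain OLS is fully specifiable and reproducible.

Degenerate (zero-variance) features return `beta = 0, p = 1` and a
`degenerate` flag rather than erroring, so matrix scans never abort.
Rank-deficient designs raise an error naming the collinear columns.

## Multiple testing

Benjamini–Hochberg step-up FDR is used throughout. For sub-gene levels
(exons, transcripts) the per-gene recalibration keeps only each gene's
smallest-p feature (ties broken by lexicographically smallest feature id)
and re-runs BH over the selected rows, one per gene, so genes with many
exons do not inflate the correction burden. Discovery thresholds:
FDR < 0.1 for differential expression and eQT-Scores, FDR < 0.05 for
eQTL pairs (pooled across all tested cis pairs), FDR ≤ 0.05 for pathway
over-representation. All are exposed as configuration knobs.

**A caveat worth knowing.** The min-p selection step is anti-conservative
under a global null: the smallest p-value among k exons of a null gene is
stochastically smaller than uniform, so BH over selected min-p values
rejects more often than its nominal level. With 10 independent exons per
gene and 300 genes, a null cohort produces at least one gene-level
"discovery" at q < 0.1 in the large majority of runs; strong within-gene
exon correlation attenuates but never removes the effect (the floor is
the BH global-null rejection probability, which equals q). The procedure
is implemented exactly as specified; its null behavior is characterized
by the test suite rather than hidden, and users should interpret
gene-level counts from the recalibration as a ranking device rather than
a calibrated FWER control.

## cis-eQTL scan

SNPs are mean-imputed per SNP (missing calls), then filtered at MAF
strictly greater than 0.05. A SNP/feature pair is tested when the SNP
lies within 1 Mb of the feature span (both ends anchor the window;
distance 0 inside the span). FDR pools all tested pairs at a given
expression level; an "eQTL gene" has at least one significant pair on any
of its features.

## Polygenic risk scores and eQT-Scores

Scores follow clumping + thresholding: GWAS SNPs are aligned to cohort
ref/alt labels (effect allele = alt passes dosages through, effect allele
= ref flips to `2 - d`; mismatching and strand-ambiguous A/T, C/G SNPs
are dropped and counted), greedily clumped by ascending GWAS p at r² >
0.1 within 250 kb (conventional defaults; clumping is optional because
the synthetic panel has no LD), and summed with weights `beta_j` over
SNPs with p ≤ 0.01 (inclusive). The score is a weighted sum, not an
average; an optional z-standardization flag exists because eQT-Score
t-statistics are scale-invariant either way (tested).

The eQT-Score replaces the diagnosis predictor with a PRS, keeping the
full covariate set (diagnosis itself is not a covariate), runs on the
entire sample, and applies the same per-gene recalibration. Significant
genes from the psychiatric scores are unioned into a joint set with
per-GWAS provenance; a non-psychiatric score serves as negative control
and never enters the joint set.

## Enrichment analyses

*MAF-matched permutation enrichment.* eSNP and background MAFs are binned
in increments of 0.05 on the 0–1 scale (half-open bins, closed top bin;
with MAF ≤ 0.5 the upper ten bins are simply empty). Each of the
permutations (default 10 000) draws background SNPs without replacement
matching the eSNP set's per-bin histogram exactly, so allele-frequency
differences between the eSNP set and the background cannot masquerade as
annotation enrichment — the motivating property, demonstrated in tests
with a deliberately MAF-confounded annotation that inflates the naive
total-count resampler (mean OR > 1.2) but not the matched one. The odds
ratio is observed overlap / mean null overlap; the empirical p-value uses
add-one smoothing `(1 + #{null >= observed}) / (1 + n_perm)`, which can
never be exactly zero. (A strict-exceedance variant is available behind a
flag.) When both the observed and mean null overlap are zero the OR is
reported as 1 (neutral); infinite when only the null mean is zero.

*Core genes.* Exact three-way intersection (no case folding) of exon-eQTL
genes, joint eQT-Score genes and a rare-variant gene list, sorted.

*Pathways.* Upper-tail hypergeometric over-representation against a
user-supplied background, sets intersected with the background first, BH
FDR across sets, fold enrichment `(k/n)/(K/N)`.

## Cell-type enrichment

Cells are scored by the mean normalized expression of the detected
members of a gene set (detected/requested counts are reported). The top
`ceil(0.25 n)` cells under the core-gene score are compared with the top
quantile under the background-gene score; ties at the cutoff break by
ascending cell id so the set size is exact. Per cell type, a one-sided
Fisher's exact test (enrichment) is applied to the 2x2 table of
core-top/background-top membership by type, with BH FDR across types and
a p < 0.05 significance call. An `all_cells` comparator is available
behind a flag for users who prefer contrasting against the full
population. Input expression is assumed already normalized/log-scale.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions for every test.

* **Genotypes.** Hard-call dosages Binomial(2, f) under Hardy–Weinberg,
  f uniform in (0.05, 0.5), 300 SNPs spaced 20 kb apart on one synthetic
  chromosome; ref/alt pairs avoid strand-ambiguous combinations. Metadata
  MAF is recomputed from the realized matrix.
* **Annotation.** 150 non-overlapping genes, 4–8 exons each (200 bp exons,
  800 bp introns, 20 kb intergenic gaps), exons partitioned among 1–3
  transcripts. Transcript values are means of member exons and gene
  values means of all the gene's exons, so one effect exon among k is
  diluted exactly k-fold at the gene level when noise is zero — the lever
  behind the exon-versus-gene detection gap the pipeline is built around.
* **Expression.** Exon value = baseline + planted eQTL, diagnosis and
  PRS-liability effects + covariate effects + noise. The noise splits
  into a per-gene shared factor and exon-specific noise (50%/50% of a
  unit total variance by default) because exon probesets of one gene are
  strongly co-expressed on arrays; without that correlation the per-gene
  min-p recalibration would behave far more anti-conservatively than it
  does on real data. The surrogate-variable covariate affects a random
  20% of exons and is handed to models as known.
* **Genetic risk.** The psychiatric GWASs (BD-, MDD- and SCZ-like) share
  one causal-SNP set (50 SNPs) with independent N(0, 0.3) effects — a
  shared-architecture caricature; the negative control (T2D-like) gets a
  disjoint causal set and no expression effects. Observed summary
  statistics add N(0, se=0.05) estimation noise with valid two-sided
  p-values (uniform under the null, KS-tested). Diagnosis is
  Bernoulli(sigmoid(1.5 × standardized mean psychiatric liability)).
* **Planted truth.** A configurable set of "core" genes carries all three
  evidence types: one eQTL exon (|beta| = 0.8 per allele on the nearest
  free SNP), PRS-target exons, and membership in the rare-variant list
  (core genes plus random filler). PRS-target genes receive the effect on
  2 exons each, matching the empirically observed ~1.5 significant exons
  per eQT-Score gene in this design's source analyses. Effect sizes were
  chosen once for adequate power at n = 200 — they are test conditions,
  not claims about real effect-size distributions.
* **Cells.** Log-normal expression for 3 000 labelled cells across 8
  types; cells of a target type have the planted gene set's means
  multiplied by a fold factor (2 by default).

All randomness flows from a single master seed through per-stage child
generators derived via CRC32-tagged seed sequences, so identical
configurations are bit-identical; the end-to-end pipeline writes
byte-identical outputs for identical seeds (tested), and the run manifest
(parameters, seed, version, per-file checksums) suffices to re-execute a
run.

**What the generator does not emulate:** linkage disequilibrium (beyond
optional duplicated SNPs for clumping tests), array-specific noise,
read-level single-cell counts, ancestry structure, or realistic
effect-size distributions. Passing tests therefore demonstrate correctness
of the procedures and their calibration under clean conditions, not
performance on real cohorts.

## Numerical conventions and problem sizes

Tabular outputs are TSV with stable column order; floats carry 6
significant digits and p-values scientific notation. VCF and annotation
coordinates are 1-based inclusive; BED is 0-based half-open, reconciled
in exactly one function (`snp_in_intervals`). Test and acceptance runs
use desk-scale cohorts (n = 200 samples, 100–300 genes, up to ~3 000
exons, 20 seeds per property, 1 000–10 000 permutations per enrichment
run); these sizes are the package's chosen study conditions and complete
in well under a minute per property on one CPU.

## Known limitations

* The per-gene min-p recalibration is not null-calibrated (see above);
  the test suite quantifies this rather than masking it.
* Clumping is O(retained × candidates) with dense r² computation —
  adequate for cohort-scale panels, not for millions of SNPs.
* The cis scan fits one solve per SNP; for very dense cis windows a
  MatrixEQTL-style single-pass factorization would be faster.
* The negative-control contract ("zero hits") inherits the BH global-null
  rejection probability (= q per run); occasional single-gene hits in a
  control scan are expected behavior, not bugs.
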
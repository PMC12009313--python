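# exqtl

Exon-level eQTL mapping, polygenic eQT-Scores and multi-modal core-gene
integration for cross-disorder psychiatric transcriptomics.

## What this package is for

Psychiatric disorders (bipolar disorder, major depression, schizophrenia)
share genetic architecture, and much of the regulatory signal in cortical
expression data lives *below* the gene level: a variant may shift one
exon of a multi-exon gene while the gene-level average stays flat.
`exqtl` is a reusable, tested pipeline for the analysis design that
exploits this:

1. **Differential expression** at gene, transcript and exon level with a
   covariate-adjusted linear model (age, sex, pH, PMI, RIN, RIN²,
   suicide, cause of death, ancestry dimensions, surrogate variable) and
   a per-gene FDR recalibration that keeps only each gene's smallest-p
   sub-feature before Benjamini–Hochberg correction.
2. **cis-eQTL mapping**: additive dosage model for every SNP (MAF > 5%)
   within 1 Mb of a feature, FDR < 5% pooled over tested pairs.
3. **Polygenic risk scores** by clumping + thresholding (p ≤ 0.01) from
   GWAS summary statistics, with allele alignment and flip invariance.
4. **Exon eQT-Scores**: the same linear model with the diagnosis replaced
   by a PRS — a joint-SNP statistic linking cumulative genetic risk to
   exon expression — run per GWAS, unioned into a joint gene set, with a
   non-psychiatric PRS as negative control.
5. **Core genes**: the intersection of exon-eQTL genes, joint eQT-Score
   genes and a rare-variant gene list — genes supported by common
   regulatory, polygenic and rare disruptive evidence simultaneously.
6. **Enrichment**: MAF-bin-matched permutation enrichment of eSNP sets
   against SNP annotations (10 000 permutations, odds ratio = observed /
   mean null overlap), and hypergeometric pathway over-representation
   against a user background.
7. **Cell-type enrichment** in labelled single-nucleus data: top-25%
   cells by mean expression of the core set vs the background set,
   one-sided Fisher's exact test per cell type.

Real cohorts of this kind are access-controlled, so the package ships a
first-class **synthetic cohort generator** (genotypes under
Hardy–Weinberg, hierarchical gene→transcript→exon expression with
plantable single-exon effects, liability-based diagnosis, noisy GWAS
summary statistics, rare-gene lists, labelled cell matrices) with a
recorded truth table, and every stage is validated against it.

## The statistic at the core

For feature *j* with expression *y<sub>j</sub>*, predictor *x* (diagnosis,
dosage, or PRS) and covariates *C*:

y<sub>j</sub> = β₀ + β₁x + Cγ + ε,  with t = β̂₁/se(β̂₁) on n − p df.

Sub-gene FDR recalibration: per gene g with features F(g), select
f\*(g) = argmin<sub>f∈F(g)</sub> p<sub>f</sub>, then apply BH to
{p<sub>f\*(g)</sub>} with m = #genes. PRS:
S<sub>i</sub> = Σ<sub>j: p<sub>j</sub>≤0.01</sub> β̂<sub>j</sub>·d<sub>ij</sub>
over clumped, allele-aligned SNPs. Enrichment OR = observed overlap /
mean MAF-matched null overlap, p = (1 + #{null ≥ obs})/(1 + N).

## Worked example

Run the whole pipeline on a synthetic cohort (200 samples, 150 genes,
~900 exons, 300 SNPs, 3 000 cells):

```bash
exqtl all --out run1 --seed 1
```

or from Python:

```python
from exqtl.pipeline import RunConfig, run_pipeline
run = run_pipeline(RunConfig(seed=1, out_dir="run1"))
```

With seed 1 this prints (via the run log and output tables):

| quantity | value | meaning |
|---|---|---|
| exon-level DE genes (FDR<0.1) | 57 | gene-level finds **0**, transcript-level 6 — single-exon effects are invisible after gene averaging |
| significant eQTL pairs (gene/transcript/exon) | 0 / 11 / 52 | detection grows with feature resolution; 47 exon-eQTL genes |
| joint eQT-Score genes | 65 | union over the BD/MDD/SCZ-like scores; the T2D-like negative control finds 1 |
| core genes | 10 | intersection of exon-eQTL ∩ joint eQT-Score ∩ rare-variant lists; recovers 100% of the 10 triple-planted truth genes |
| eSNP enrichment OR (random annotation) | 0.998 (p = 0.57) | the MAF-matched null is calibrated |
| top cell type | Ex1, OR 1.86, p = 2.4e-9 | the type carrying the planted 2× core-gene upregulation |

Every output is a TSV/JSON file in `run1/` plus a `manifest.json` with
parameters, seed and per-file checksums; identical seeds give
byte-identical outputs. Individual stages are available as subcommands
(`exqtl de`, `exqtl eqtl`, `exqtl prs`, `exqtl eqtscore`,
`exqtl core-genes`, `exqtl enrich-snps`, `exqtl enrich-pathways`,
`exqtl celltype`) operating on standard formats: VCF or dosage TSV,
expression/covariate/annotation TSV, GWAS summary TSV, BED, GMT, and
MatrixMarket MTX bundles for single-cell data.

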
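"""Synthetic cohort generator with known ground truth.

Every downstream stage of the pipeline (differential expression, cis-eQTL
scan, polygenic scoring, eQT-Score, enrichment, cell-type analysis) is
exercised on cohorts produced here, so each planted effect is recorded in
a :class:`TruthTable` that tests can cross-reference.

The generative model, briefly:

* Genotypes are hard-call dosages drawn ``Binomial(2, f)`` under
  Hardy-Weinberg with per-SNP allele frequencies uniform in a configured
  MAF range, laid out equally spaced along one synthetic chromosome.
* Gene models are non-overlapping intervals on the same chromosome; each
  gene carries a configurable number of exons partitioned among its
  transcripts.  Exon expression is::

      e_ij = mu_j + dosage_i(snp(j)) * b_eqtl(j) + diag_i * b_de(j)
             + liability_i(g) * b_prs(j) + covariates_i @ gamma_j + eps_ij

  where the noise ``eps`` is split between a per-gene shared factor and
  exon-specific noise (exon probesets of one gene are strongly
  co-expressed on arrays, and the per-gene lowest-p FDR recalibration
  downstream implicitly relies on that).  Transcript values are the mean
  of their member exons and gene values the mean of all the gene's exons,
  so a single-exon effect is diluted exactly by the exon count.
* Each configured GWAS gets a causal-SNP set with normal effect sizes;
  psychiatric GWASs share one causal set (shared genetic architecture),
  the negative control gets a disjoint one.  Observed summary statistics
  add normal estimation noise with valid two-sided p-values.  Diagnosis
  is Bernoulli(sigmoid(w * liability)) on the standardized mean
  psychiatric liability.
* A rare-variant gene list mixes the designated core genes with random
  filler genes, and a labelled cell x gene matrix supports plantable
  cell-type-specific upregulation of a gene set.

All randomness flows from a single master seed through deterministically
derived per-stage child generators, so identical configurations are
bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .association import covariate_design
from .containers import CellMatrix, GenotypeMatrix
from .errors import ConfigError, InputError

_BASES = ["A", "C", "G", "T"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_CELL_TYPES = ("Ex1", "Ex2", "Ex3", "Ex4", "In1", "In2", "Oligo", "OPC")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    # genotypes
    n_samples: int = 200
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    spacing_bp: int = 20_000
    # annotation
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (4, 8)
    n_transcripts_per_gene: tuple[int, int] = (1, 3)
    # planted effects
    frac_eqtl_exons: float = 0.05
    eqtl_beta: float = 0.8
    frac_de_exons: float = 0.05
    de_beta: float = 0.5
    frac_prs_exons: float = 0.04
    prs_expr_beta: float = 0.4
    prs_exons_per_gene: int = 2
    # genetic risk
    n_causal_prs_snps: int = 50
    prs_liability_weight: float = 1.5
    gwas_se: float = 0.05
    gwas_names: tuple[str, ...] = ("BD", "MDD", "SCZ")
    negative_control: str = "T2D"
    # noise
    noise_sd: float = 1.0
    gene_factor_frac: float = 0.5
    covariate_effect_sd: float = 0.1
    # core / rare genes
    n_core_genes: int = 10
    n_rare_genes: int = 30
    # single-cell
    n_cells: int = 3000
    cell_type_labels: tuple[str, ...] = DEFAULT_CELL_TYPES
    cell_type_props: tuple[float, ...] | None = None
    celltype_bias_factor: float = 2.0
    celltype_bias_target: str = "Ex1"
    # pathway sets
    n_pathways: int = 10
    pathway_size: tuple[int, int] = (10, 40)

    def validate(self) -> "SimConfig":
        counts = {
            "n_samples": self.n_samples, "n_snps": self.n_snps,
            "n_genes": self.n_genes, "n_cells": self.n_cells,
            "spacing_bp": self.spacing_bp,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        for name in ("frac_eqtl_exons", "frac_de_exons", "frac_prs_exons", "gene_factor_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("exons_per_gene", "n_transcripts_per_gene", "pathway_size"):
            a, b = getattr(self, name)
            if not (0 < a <= b):
                raise ConfigError(f"{name} range invalid: {getattr(self, name)}")
        if self.frac_eqtl_exons > 0 and self.n_snps == 0:
            raise ConfigError("frac_eqtl_exons > 0 requires n_snps > 0")
        if self.noise_sd < 0 or self.covariate_effect_sd < 0:
            raise ConfigError("noise and covariate effect scales must be non-negative")
        if self.celltype_bias_factor < 1:
            raise ConfigError("celltype_bias_factor must be >= 1")
        if self.celltype_bias_target not in self.cell_type_labels:
            raise ConfigError(f"unknown celltype_bias_target {self.celltype_bias_target!r}")
        if self.cell_type_props is not None:
            props = np.asarray(self.cell_type_props, dtype=float)
            if len(props) != len(self.cell_type_labels) or abs(props.sum() - 1) > 1e-9:
                raise ConfigError("cell_type_props must match labels and sum to 1")
        if self.n_core_genes > self.n_genes or self.n_rare_genes > self.n_genes:
            raise ConfigError("core/rare gene counts exceed n_genes")
        if self.n_causal_prs_snps < 0 or 2 * self.n_causal_prs_snps > self.n_snps:
            raise ConfigError("need n_snps >= 2 * n_causal_prs_snps (psychiatric + control causal sets)")
        return self


@dataclass
class TruthTable:
    """Planted ground truth of one simulated cohort."""

    eqtl: pd.DataFrame        # exon_id, snp_id, beta
    de: pd.DataFrame          # exon_id, beta
    prs: pd.DataFrame         # exon_id, gwas, beta
    causal: pd.DataFrame      # gwas, snp_id, beta
    liability: pd.DataFrame   # samples x (one column per GWAS + "diagnosis")
    core_genes: list[str]
    rare_genes: list[str]
    biased_cell_type: str | None = None


@dataclass
class SimBundle:
    """Everything one simulated cohort produces."""

    config: SimConfig
    genotypes: GenotypeMatrix
    features: pd.DataFrame
    exon_expr: pd.DataFrame
    transcript_expr: pd.DataFrame
    gene_expr: pd.DataFrame
    covariates: pd.DataFrame
    diagnosis: pd.Series
    gwas: dict[str, pd.DataFrame]
    rare_genes: list[str]
    truth: TruthTable


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         zlib.crc32(tag.encode())]))


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def simulate_genotypes(n_samples: int, n_snps: int, maf_range=(0.05, 0.5),
                       spacing_bp: int = 20_000, seed: int = 0) -> GenotypeMatrix:
    """Hardy-Weinberg dosages on one synthetic chromosome.

    SNP ``j`` (0-based) sits at position ``(j + 1) * spacing_bp``; its
    alt-allele frequency is uniform in ``maf_range`` and the metadata MAF
    is recomputed from the realized matrix.
    """
    if n_samples < 2 or n_snps < 1:
        raise ConfigError("need n_samples >= 2 and n_snps >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigError(f"invalid maf_range {maf_range}")
    if spacing_bp <= 0:
        raise ConfigError("spacing_bp must be positive")
    rng = child_rng(seed, "genotypes")
    freqs = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(float)
    snp_ids = [f"rs{j:06d}" for j in range(1, n_snps + 1)]
    refs = rng.choice(_BASES, size=n_snps)
    # alt differs from ref and is never its strand complement (keeps the
    # simulated panel free of strand-ambiguous A/T and C/G pairs)
    alts = np.array([
        rng.choice([b for b in _BASES if b != r and b != _COMPLEMENT[r]])
        for r in refs
    ])
    realized = dosages.sum(axis=0) / (2 * n_samples)
    snps = pd.DataFrame({
        "chrom": "1",
        "pos": (np.arange(n_snps) + 1) * spacing_bp,
        "ref": refs,
        "alt": alts,
        "maf": np.minimum(realized, 1 - realized),
    }, index=pd.Index(snp_ids, name="snp_id"))
    dmat = pd.DataFrame(dosages, index=_sample_ids(n_samples), columns=snp_ids)
    return GenotypeMatrix(dosages=dmat, snps=snps)


def simulate_annotation(n_genes: int, exons_per_gene=(4, 8),
                        n_transcripts_per_gene=(1, 3), seed: int = 0,
                        exon_len: int = 200, intron_len: int = 800,
                        intergenic_gap: int = 20_000) -> pd.DataFrame:
    """Non-overlapping gene models with exon/transcript hierarchy.

    Returns the annotation frame (one row per gene, transcript and exon;
    1-based inclusive coordinates).  Exons are partitioned among the
    gene's transcripts so every exon belongs to exactly one transcript.
    """
    if n_genes <= 0:
        raise ConfigError("n_genes must be positive")
    for rng_pair in (exons_per_gene, n_transcripts_per_gene):
        if rng_pair[0] > rng_pair[1] or rng_pair[0] < 1:
            raise ConfigError(f"invalid range {rng_pair}")
    rng = child_rng(seed, "annotation")
    rows = []
    pos = 10_001
    for g in range(1, n_genes + 1):
        gene_id = f"G{g:04d}"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_tx = int(rng.integers(n_transcripts_per_gene[0], n_transcripts_per_gene[1] + 1))
        n_tx = min(n_tx, n_exons)
        # partition exons among transcripts, every transcript non-empty
        assignment = np.concatenate([np.arange(n_tx), rng.integers(0, n_tx, size=n_exons - n_tx)])
        rng.shuffle(assignment)
        gene_start = pos
        exon_rows = []
        for e in range(n_exons):
            start = pos
            end = start + exon_len - 1
            tx_id = f"{gene_id}.T{assignment[e] + 1}"
            exon_rows.append((f"{gene_id}.E{e + 1:02d}", gene_id, tx_id, "exon", "1", start, end))
            pos = end + 1 + intron_len
        gene_end = exon_rows[-1][6]
        rows.append((gene_id, gene_id, "", "gene", "1", gene_start, gene_end))
        for t in range(1, n_tx + 1):
            tx_id = f"{gene_id}.T{t}"
            member = [r for r in exon_rows if r[2] == tx_id]
            rows.append((tx_id, gene_id, tx_id, "transcript", "1",
                         min(r[5] for r in member), max(r[6] for r in member)))
        rows.extend(exon_rows)
        pos = gene_end + 1 + intergenic_gap
    features = pd.DataFrame(rows, columns=["feature_id", "gene_id", "transcript_id",
                                           "level", "chrom", "start", "end"])
    return features


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cod = rng.choice(["natural", "violent", "non-violent"], size=n, p=[0.5, 0.25, 0.25])
    cov = pd.DataFrame({
        "age": rng.uniform(18, 87, n).round(1),
        "sex": rng.integers(0, 2, n).astype(float),
        "pH": rng.normal(6.5, 0.25, n).round(3),
        "PMI": rng.uniform(5, 50, n).round(1),
        "RIN": rng.uniform(6, 9, n).round(2),
        "suicide": (rng.random(n) < 0.25).astype(float),
        "CoD": cod,
        "Dim1": rng.normal(0, 0.01, n),
        "Dim2": rng.normal(0, 0.01, n),
        "Dim3": rng.normal(0, 0.01, n),
        "Dim4": rng.normal(0, 0.01, n),
        "SV1": rng.normal(0, 1, n),
    }, index=_sample_ids(n))
    cov.insert(5, "RIN2", cov["RIN"] ** 2)
    cov.index.name = "sample_id"
    return cov


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _gwas_table(geno: GenotypeMatrix, true_beta: np.ndarray, se: float,
                rng: np.random.Generator) -> pd.DataFrame:
    from scipy import stats
    if se <= 0:
        beta_hat = true_beta.astype(float)
        p = np.where(true_beta != 0, 1e-300, 1.0)
    else:
        beta_hat = true_beta + rng.normal(0, se, size=len(true_beta))
        z = beta_hat / se
        p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    snps = geno.snps
    return pd.DataFrame({
        "snp_id": snps.index,
        "chrom": snps["chrom"].to_numpy(),
        "pos": snps["pos"].to_numpy(),
        "A1": snps["alt"].to_numpy(),   # effect allele = alt
        "A2": snps["ref"].to_numpy(),
        "beta": beta_hat,
        "se": se,
        "p": p,
    }).reset_index(drop=True)


def simulate_cohort(config: SimConfig) -> SimBundle:
    """Generate the full bundle for one cohort; see the module docstring."""
    cfg = config.validate()
    seed = cfg.seed

    geno = simulate_genotypes(cfg.n_samples, cfg.n_snps, cfg.maf_range,
                              cfg.spacing_bp, seed=seed)
    features = simulate_annotation(cfg.n_genes, cfg.exons_per_gene,
                                   cfg.n_transcripts_per_gene, seed=seed)
    exons = features[features["level"] == "exon"].reset_index(drop=True)
    n_exons = len(exons)
    samples = geno.sample_ids
    n = cfg.n_samples

    cov = _simulate_covariates(n, child_rng(seed, "covariates"))

    # --- genetic risk: causal sets, observed GWAS, liabilities ---
    rng_risk = child_rng(seed, "risk")
    snp_ids = np.array(geno.snp_ids)
    perm = rng_risk.permutation(cfg.n_snps)
    psych_causal = np.sort(perm[:cfg.n_causal_prs_snps])
    control_causal = np.sort(perm[cfg.n_causal_prs_snps:2 * cfg.n_causal_prs_snps])
    dos = geno.dosages.to_numpy()

    gwas: dict[str, pd.DataFrame] = {}
    liab = {}
    causal_rows = []
    all_names = list(cfg.gwas_names) + ([cfg.negative_control] if cfg.negative_control else [])
    for name in all_names:
        idx = control_causal if name == cfg.negative_control else psych_causal
        true_beta = np.zeros(cfg.n_snps)
        true_beta[idx] = rng_risk.normal(0, 0.3, size=len(idx))
        gwas[name] = _gwas_table(geno, true_beta, cfg.gwas_se, child_rng(seed, f"gwas:{name}"))
        liab[name] = _standardize(dos @ true_beta)
        for j in idx:
            causal_rows.append((name, snp_ids[j], true_beta[j]))
    causal = pd.DataFrame(causal_rows, columns=["gwas", "snp_id", "beta"])

    psych_mean = np.mean([liab[nm] for nm in cfg.gwas_names], axis=0)
    diag_liab = _standardize(psych_mean)
    rng_diag = child_rng(seed, "diagnosis")
    diagnosis = pd.Series(
        (rng_diag.random(n) < expit(cfg.prs_liability_weight * diag_liab)).astype(int),
        index=samples, name="diagnosis")
    liab_df = pd.DataFrame(liab, index=samples)
    liab_df["diagnosis"] = diag_liab

    # --- choose planted exons ---
    rng_fx = child_rng(seed, "effects")
    gene_ids = exons["gene_id"].unique()
    core_genes = sorted(rng_fx.choice(gene_ids, size=cfg.n_core_genes, replace=False))
    exon_by_gene = exons.groupby("gene_id").indices

    causal_set = set(psych_causal) | set(control_causal)
    free_snps = np.array([j for j in range(cfg.n_snps) if j not in causal_set])
    snp_pos = geno.snps["pos"].to_numpy()
    exon_mid = ((exons["start"] + exons["end"]) // 2).to_numpy()

    def nearest_free_snp(exon_idx: int, used: set[int]) -> int | None:
        avail = [j for j in free_snps if j not in used]
        if not avail:
            return None
        d = np.abs(snp_pos[avail] - exon_mid[exon_idx])
        return avail[int(np.argmin(d))]

    used_snps: set[int] = set()
    eqtl_rows, de_rows, prs_rows = [], [], []
    eqtl_cols: list[np.ndarray] = []
    eqtl_betas: list[tuple[int, float]] = []   # (exon index, beta) per column
    de_effect = np.zeros(n_exons)
    prs_effect = np.zeros((n_exons, n))

    def plant_eqtl(exon_idx: int, beta: float) -> None:
        j = nearest_free_snp(exon_idx, used_snps)
        if j is None:
            return
        used_snps.add(j)
        eqtl_cols.append(dos[:, j])
        eqtl_betas.append((exon_idx, beta))
        eqtl_rows.append((exons.loc[exon_idx, "feature_id"], snp_ids[j], beta))

    def plant_prs(exon_idx: int, gwas_name: str, beta: float) -> None:
        prs_effect[exon_idx] += beta * liab[gwas_name]
        prs_rows.append((exons.loc[exon_idx, "feature_id"], gwas_name, beta))

    # core genes carry an eQTL exon and PRS-target exons (round-robin GWAS)
    for i, g in enumerate(core_genes):
        idxs = np.sort(exon_by_gene[g])
        sign = 1.0 if rng_fx.random() < 0.5 else -1.0
        plant_eqtl(int(idxs[0]), sign * cfg.eqtl_beta)
        gname = cfg.gwas_names[i % len(cfg.gwas_names)]
        psign = 1.0 if rng_fx.random() < 0.5 else -1.0
        for k in range(cfg.prs_exons_per_gene):
            plant_prs(int(idxs[min(1 + k, len(idxs) - 1)]), gname, psign * cfg.prs_expr_beta)

    # additional plantings on non-core genes
    core_set = set(core_genes)
    other_exons = exons.index[~exons["gene_id"].isin(core_set)].to_numpy()
    rng_fx.shuffle(other_exons)
    n_extra_eqtl = int(round(cfg.frac_eqtl_exons * n_exons))
    n_extra_de = int(round(cfg.frac_de_exons * n_exons))
    n_extra_prs_genes = int(round(cfg.frac_prs_exons * n_exons / max(cfg.prs_exons_per_gene, 1)))
    cursor = 0
    for _ in range(n_extra_eqtl):
        if cursor >= len(other_exons):
            break
        sign = 1.0 if rng_fx.random() < 0.5 else -1.0
        plant_eqtl(int(other_exons[cursor]), sign * cfg.eqtl_beta)
        cursor += 1
    for _ in range(n_extra_de):
        if cursor >= len(other_exons):
            break
        sign = 1.0 if rng_fx.random() < 0.5 else -1.0
        e = int(other_exons[cursor])
        de_effect[e] = sign * cfg.de_beta
        de_rows.append((exons.loc[e, "feature_id"], sign * cfg.de_beta))
        cursor += 1
    prs_target_genes = []
    other_genes = [g for g in gene_ids if g not in core_set]
    rng_fx.shuffle(other_genes)
    for g in other_genes[:n_extra_prs_genes]:
        prs_target_genes.append(g)
        idxs = np.sort(exon_by_gene[g])
        gname = cfg.gwas_names[len(prs_target_genes) % len(cfg.gwas_names)]
        psign = 1.0 if rng_fx.random() < 0.5 else -1.0
        for k in range(min(cfg.prs_exons_per_gene, len(idxs))):
            plant_prs(int(idxs[k]), gname, psign * cfg.prs_expr_beta)

    # --- assemble exon expression ---
    rng_noise = child_rng(seed, "noise")
    mu = rng_noise.normal(7.0, 1.0, size=n_exons)
    values = np.tile(mu[:, None], (1, n))
    for col, (e, b) in zip(eqtl_cols, eqtl_betas):
        values[e] += b * col
    values += de_effect[:, None] * diagnosis.to_numpy()[None, :]
    values += prs_effect

    # covariate effects on standardized covariate columns
    design = covariate_design(cov)
    dvals = design.to_numpy()
    dsd = dvals.std(axis=0)
    dsd[dsd == 0] = 1.0
    z = (dvals - dvals.mean(axis=0)) / dsd
    gamma = rng_noise.normal(0, cfg.covariate_effect_sd, size=(n_exons, z.shape[1]))
    sv_col = design.columns.get_loc("SV1")
    sv_mask = rng_noise.random(n_exons) < 0.2   # SV affects a random 20% of exons
    gamma[~sv_mask, sv_col] = 0.0
    values += gamma @ z.T

    # noise: per-gene shared factor + exon-specific, total variance noise_sd^2
    if cfg.noise_sd > 0:
        shared_sd = cfg.noise_sd * np.sqrt(cfg.gene_factor_frac)
        spec_sd = cfg.noise_sd * np.sqrt(1 - cfg.gene_factor_frac)
        gene_codes, _ = pd.factorize(exons["gene_id"])
        gfac = rng_noise.normal(0, 1.0, size=(gene_codes.max() + 1, n))
        values += shared_sd * gfac[gene_codes]
        values += spec_sd * rng_noise.normal(0, 1.0, size=(n_exons, n))

    exon_expr = pd.DataFrame(values, index=pd.Index(exons["feature_id"], name="feature_id"),
                             columns=samples)
    transcript_expr = summarize_expression(exon_expr, exons, by="transcript_id")
    gene_expr = summarize_expression(exon_expr, exons, by="gene_id")

    # --- rare-variant gene list ---
    rng_rare = child_rng(seed, "rare")
    filler = [g for g in gene_ids if g not in core_set]
    n_fill = max(cfg.n_rare_genes - len(core_genes), 0)
    rare = sorted(set(core_genes) | set(rng_rare.choice(filler, size=n_fill, replace=False)))

    truth = TruthTable(
        eqtl=pd.DataFrame(eqtl_rows, columns=["exon_id", "snp_id", "beta"]),
        de=pd.DataFrame(de_rows, columns=["exon_id", "beta"]),
        prs=pd.DataFrame(prs_rows, columns=["exon_id", "gwas", "beta"]),
        causal=causal,
        liability=liab_df,
        core_genes=list(core_genes),
        rare_genes=rare,
        biased_cell_type=cfg.celltype_bias_target,
    )
    return SimBundle(config=cfg, genotypes=geno, features=features,
                     exon_expr=exon_expr, transcript_expr=transcript_expr,
                     gene_expr=gene_expr, covariates=cov, diagnosis=diagnosis,
                     gwas=gwas, rare_genes=rare, truth=truth)


def summarize_expression(exon_expr: pd.DataFrame, exon_annot: pd.DataFrame,
                         by: str = "gene_id") -> pd.DataFrame:
    """Unweighted mean of member exons per gene or transcript."""
    key = exon_annot.set_index("feature_id")[by]
    grouped = exon_expr.groupby(exon_expr.index.map(key)).mean()
    grouped.index.name = "feature_id"
    return grouped


def validate_truth(bundle: SimBundle) -> None:
    """Cross-reference every planted id against the generated tables."""
    feats = set(bundle.features["feature_id"])
    snps = set(bundle.genotypes.snp_ids)
    genes = set(bundle.features.loc[bundle.features["level"] == "gene", "feature_id"])
    t = bundle.truth
    for e in list(t.eqtl["exon_id"]) + list(t.de["exon_id"]) + list(t.prs["exon_id"]):
        if e not in feats:
            raise InputError(f"truth exon {e} missing from feature table")
    for s in list(t.eqtl["snp_id"]) + list(t.causal["snp_id"]):
        if s not in snps:
            raise InputError(f"truth SNP {s} missing from genotype matrix")
    for g in t.core_genes + t.rare_genes:
        if g not in genes:
            raise InputError(f"truth gene {g} missing from feature table")


def simulate_cells(n_cells: int, cell_type_labels, proportions=None,
                   gene_ids=None, bias_genes=(), bias_target: str | None = None,
                   bias_factor: float = 1.0, seed: int = 0) -> CellMatrix:
    """Labelled cells x genes matrix with plantable cell-type upregulation.

    Values are log-normal (already "normalised" scale); cells of the
    ``bias_target`` type have the mean of every gene in ``bias_genes``
    multiplied by ``bias_factor``.
    """
    labels = list(cell_type_labels)
    if n_cells <= 0 or not labels:
        raise ConfigError("need n_cells > 0 and at least one cell type")
    if proportions is None:
        proportions = np.full(len(labels), 1.0 / len(labels))
    proportions = np.asarray(proportions, dtype=float)
    if len(proportions) != len(labels) or abs(proportions.sum() - 1.0) > 1e-9:
        raise ConfigError("proportions must match labels and sum to 1")
    if bias_factor < 1:
        raise ConfigError("bias_factor must be >= 1")
    if bias_target is not None and bias_target not in labels:
        raise ConfigError(f"unknown bias_target {bias_target!r}")
    gene_ids = list(gene_ids) if gene_ids is not None else [f"G{i:04d}" for i in range(1, 101)]
    bias_genes = list(bias_genes)
    unknown = [g for g in bias_genes if g not in gene_ids]
    if unknown:
        raise ConfigError(f"bias_genes not in gene_ids: {unknown[:5]}")

    rng = child_rng(seed, "cells")
    lab = rng.choice(labels, size=n_cells, p=proportions)
    vals = rng.lognormal(mean=0.0, sigma=0.5, size=(n_cells, len(gene_ids)))
    if bias_target is not None and bias_genes and bias_factor > 1:
        rows = lab == bias_target
        cols = [gene_ids.index(g) for g in bias_genes]
        vals[np.ix_(rows, cols)] *= bias_factor
    cell_ids = [f"C{i:05d}" for i in range(1, n_cells + 1)]
    expr = pd.DataFrame(vals, index=pd.Index(cell_ids, name="cell_id"), columns=gene_ids)
    return CellMatrix(expr=expr, labels=pd.Series(lab, index=expr.index, name="cell_type"))


def simulate_pathways(gene_ids, core_genes=(), n_sets: int = 10,
                      size_range=(10, 40), seed: int = 0) -> dict[str, list[str]]:
    """Gene sets over the simulated genes; the first set is enriched in
    the core genes so pathway over-representation has signal to find."""
    rng = child_rng(seed, "pathways")
    gene_ids = list(gene_ids)
    core = [g for g in core_genes if g in gene_ids]
    sets: dict[str, list[str]] = {}
    lo, hi = size_range
    for i in range(1, n_sets + 1):
        size = min(int(rng.integers(lo, hi + 1)), len(gene_ids))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        if i == 1:
            members |= set(core)
        sets[f"PATH{i:03d}"] = sorted(members)
    return sets
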
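"""Clumping + thresholding polygenic risk scores.

The score of sample *i* is the weighted sum of effect-allele dosages
over GWAS SNPs passing the p-value threshold (p <= 0.01 by default,
inclusive) after greedy LD clumping::

    score_i = sum_j beta_j * effective_dosage_ij

Effect alleles are aligned to the cohort's ref/alt labels: when the GWAS
effect allele A1 equals the alt allele the dosage passes through, when it
equals the ref allele the dosage is flipped to ``2 - d``, and SNPs whose
alleles do not match or that are strand-ambiguous (A/T, C/G) are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import InputError

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_R2 = 0.1
DEFAULT_WINDOW_KB = 250


def align_alleles(gwas: pd.DataFrame, snps: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Match GWAS effect alleles against cohort ref/alt labels.

    Returns (aligned table with columns snp_id, beta, p, flip) and a
    counts dict: matched, flipped, mismatch, ambiguous, absent.
    """
    if gwas["snp_id"].duplicated().any():
        dup = gwas.loc[gwas["snp_id"].duplicated(), "snp_id"].tolist()
        raise InputError(f"duplicate snp_id in GWAS: {dup[:5]}")
    counts = {"matched": 0, "flipped": 0, "mismatch": 0, "ambiguous": 0, "absent": 0}
    rows = []
    for row in gwas.itertuples(index=False):
        sid = row.snp_id
        if sid not in snps.index:
            counts["absent"] += 1
            continue
        a1, a2 = str(row.A1).upper(), str(row.A2).upper()
        if frozenset((a1, a2)) in _AMBIGUOUS:
            counts["ambiguous"] += 1
            continue
        ref, alt = snps.loc[sid, "ref"], snps.loc[sid, "alt"]
        if a1 == alt and a2 == ref:
            rows.append((sid, float(row.beta), float(row.p), False))
            counts["matched"] += 1
        elif a1 == ref and a2 == alt:
            rows.append((sid, float(row.beta), float(row.p), True))
            counts["flipped"] += 1
        else:
            counts["mismatch"] += 1
    aligned = pd.DataFrame(rows, columns=["snp_id", "beta", "p", "flip"])
    return aligned, counts


def greedy_clump(gwas: pd.DataFrame, geno: GenotypeMatrix,
                 r2_threshold: float = DEFAULT_R2,
                 window_kb: float = DEFAULT_WINDOW_KB) -> list[str]:
    """PRSice-style greedy LD clumping by ascending GWAS p-value.

    A SNP is retained unless its dosage r^2 with an already-retained SNP
    within ``window_kb`` exceeds ``r2_threshold``.  SNPs absent from the
    cohort genotypes are retained without an LD check.
    """
    if gwas.empty:
        return []
    geno = geno.imputed()
    dos = geno.dosages
    pos = geno.snps["pos"]
    chrom = geno.snps["chrom"]
    order = gwas.sort_values(["p", "snp_id"], kind="stable")
    retained: list[str] = []
    window = window_kb * 1000
    for row in order.itertuples(index=False):
        sid = row.snp_id
        if sid not in dos.columns:
            retained.append(sid)
            continue
        x = dos[sid].to_numpy()
        keep = True
        for other in retained:
            if other not in dos.columns:
                continue
            if chrom[other] != chrom[sid] or abs(pos[other] - pos[sid]) > window:
                continue
            y = dos[other].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_threshold:
                keep = False
                break
        if keep:
            retained.append(sid)
    return retained


@dataclass
class PrsResult:
    """Per-sample scores for one GWAS plus bookkeeping."""

    scores: pd.Series
    n_snps_used: int
    align_counts: dict = field(default_factory=dict)


def compute_prs(geno: GenotypeMatrix, gwas: pd.DataFrame,
                p_threshold: float = DEFAULT_P_THRESHOLD, clump: bool = True,
                standardize: bool = False, r2_threshold: float = DEFAULT_R2,
                window_kb: float = DEFAULT_WINDOW_KB,
                name: str = "PRS") -> PrsResult:
    """Weighted effect-allele dosage sum over thresholded (clumped) SNPs."""
    aligned, counts = align_alleles(gwas, geno.snps)
    if clump and not aligned.empty:
        kept = set(greedy_clump(aligned, geno, r2_threshold, window_kb))
        aligned = aligned[aligned["snp_id"].isin(kept)]
    aligned = aligned[aligned["p"] <= p_threshold]   # inclusive threshold
    geno = geno.imputed()
    if aligned.empty:
        warnings.warn(f"no SNPs pass p <= {p_threshold}; scores are all zero")
        scores = pd.Series(0.0, index=geno.sample_ids, name=name)
        return PrsResult(scores=scores, n_snps_used=0, align_counts=counts)
    aligned = aligned.sort_values("snp_id", kind="stable")
    dos = geno.dosages[aligned["snp_id"]].to_numpy(dtype=float)
    flip = aligned["flip"].to_numpy()
    eff = np.where(flip[None, :], 2.0 - dos, dos)
    vals = eff @ aligned["beta"].to_numpy()
    if standardize:
        sd = vals.std()
        vals = (vals - vals.mean()) / sd if sd > 0 else vals - vals.mean()
    scores = pd.Series(vals, index=geno.sample_ids, name=name)
    return PrsResult(scores=scores, n_snps_used=len(aligned), align_counts=counts)


def prs_table(geno: GenotypeMatrix, gwas_tables: dict[str, pd.DataFrame],
              **kwargs) -> pd.DataFrame:
    """Samples x GWAS table of scores (one column per GWAS name)."""
    cols = {}
    for gname in gwas_tables:
        cols[gname] = compute_prs(geno, gwas_tables[gname], name=gname, **kwargs).scores
    out = pd.DataFrame(cols)
    out.index.name = "sample_id"
    return out
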
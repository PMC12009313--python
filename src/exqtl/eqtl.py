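"""cis-eQTL scanning.

SNPs passing a strict minor-allele-frequency filter (MAF > 0.05 by
default) are paired with every expression feature whose span lies within
a 1 Mb window, each pair is fit with the shared covariate-adjusted
additive linear model (expression ~ dosage), and Benjamini-Hochberg FDR
is computed in one pool across all tested pairs.  A feature-level "eQTL
gene" list collects genes with at least one significant pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import attach_fdr, fit_matrix_association
from .containers import GenotypeMatrix, validate_feature_table
from .errors import InputError

DEFAULT_WINDOW = 1_000_000
DEFAULT_MAF_MIN = 0.05
DEFAULT_FDR = 0.05


def compute_maf(dosages) -> float:
    """Minor-allele frequency from additive dosages.

    Accepts fractional dosages in [0, 2] (mean-imputed missing calls are
    fractional); values outside that range are rejected.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise InputError("empty dosage vector")
    if np.any(np.isnan(d)) or np.any((d < 0) | (d > 2)):
        raise InputError("dosages must lie in [0, 2] after imputation")
    f = d.sum() / (2 * d.size)
    return float(min(f, 1 - f))


def enumerate_cis_pairs(snps: pd.DataFrame, features: pd.DataFrame,
                        window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """All (snp, feature) pairs with the SNP within ``window`` bp of the
    feature span on the same chromosome.

    ``distance`` is 0 when the SNP lies inside [start, end], otherwise
    the distance to the nearer boundary.
    """
    if window < 0:
        raise InputError("window must be >= 0")
    out = []
    pos_by_chrom = {c: sub for c, sub in snps.groupby("chrom")}
    for _, feat in features.iterrows():
        sub = pos_by_chrom.get(feat["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = feat["start"] - window, feat["end"] + window
        mask = (pos >= lo) & (pos <= hi)
        if not mask.any():
            continue
        p = pos[mask]
        dist = np.where((p >= feat["start"]) & (p <= feat["end"]), 0,
                        np.minimum(np.abs(p - feat["start"]), np.abs(p - feat["end"])))
        out.append(pd.DataFrame({
            "snp_id": sub.index[mask],
            "feature_id": feat["feature_id"],
            "distance": dist.astype(int),
        }))
    if not out:
        return pd.DataFrame(columns=["snp_id", "feature_id", "distance"])
    return pd.concat(out, ignore_index=True)


@dataclass
class EqtlResult:
    """Pair-level association table plus the derived eQTL-gene list."""

    pairs: pd.DataFrame
    eqtl_genes: list[str]
    n_snps_tested: int
    n_pairs_tested: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def run_cis_eqtl(geno: GenotypeMatrix, Y: pd.DataFrame, covars: pd.DataFrame,
                 features: pd.DataFrame, window: int = DEFAULT_WINDOW,
                 maf_min: float = DEFAULT_MAF_MIN,
                 fdr_threshold: float = DEFAULT_FDR) -> EqtlResult:
    """Full cis scan of one expression level against all retained SNPs.

    Samples are intersected by id across genotypes, expression and
    covariates (order-independent); missing dosages are mean-imputed per
    SNP before the strict MAF filter; FDR pools all tested pairs.
    """
    if not 0 <= maf_min <= 0.5:
        raise InputError("maf_min must lie in [0, 0.5]")
    features = validate_feature_table(features)
    shared = sorted(set(geno.sample_ids) & set(Y.columns) & set(covars.index))
    if not shared:
        raise InputError("no overlapping samples between genotypes, expression and covariates")
    geno = geno.subset_samples(shared).imputed()
    Y = Y[shared]
    covars = covars.loc[shared]

    dos = geno.dosages
    maf = dos.apply(lambda c: compute_maf(c.to_numpy()), axis=0)
    keep = maf[maf > maf_min].index   # strictly greater, per the filter contract
    feat_sub = features[features["feature_id"].isin(Y.index)]
    pairs = enumerate_cis_pairs(geno.snps.loc[keep], feat_sub, window)

    tables = []
    gene_of = features.set_index("feature_id")["gene_id"]
    for snp_id, grp in pairs.groupby("snp_id", sort=True):
        sub = Y.loc[grp["feature_id"]]
        t = fit_matrix_association(sub, dos[snp_id].to_numpy(), covars,
                                   predictor=snp_id)
        t = t.rename(columns={"predictor": "snp_id"})
        tables.append(t)
    if tables:
        result = pd.concat(tables, ignore_index=True)
        result = result.sort_values(["snp_id", "feature_id"], kind="stable").reset_index(drop=True)
        result = attach_fdr(result)
        result["significant"] = result["fdr"] < fdr_threshold
        result.insert(2, "gene_id", result["feature_id"].map(gene_of))
    else:
        result = pd.DataFrame(columns=["feature_id", "snp_id", "gene_id", "beta", "se",
                                       "t", "df", "p", "degenerate", "fdr", "significant"])
    genes = sorted(result.loc[result["significant"], "gene_id"].unique())
    return EqtlResult(pairs=result, eqtl_genes=genes,
                      n_snps_tested=len(keep), n_pairs_tested=len(result))
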
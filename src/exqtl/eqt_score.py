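"""Exon eQT-Score: polygenic-score x exon-expression association.

The eQT-Score replaces the diagnosis predictor of the differential
expression model with a per-sample polygenic risk score, keeping the
full covariate set, and applies the same per-gene lowest-p FDR
recalibration.  Scores for several psychiatric GWASs are run separately
and their significant genes unioned into a joint set with per-GWAS
provenance; a non-psychiatric score (e.g. type-2 diabetes) serves as a
negative control and is never part of the joint set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import fit_matrix_association, multilevel_fdr
from .containers import validate_feature_table
from .errors import InputError

DEFAULT_FDR = 0.1


@dataclass
class EqtScoreResult:
    """Per-GWAS exon- and gene-level association outcome."""

    gwas_name: str
    exon_table: pd.DataFrame
    gene_table: pd.DataFrame
    significant_genes: list[str]
    significant_exons: list[str]


def run_eqt_score(Y_exon: pd.DataFrame, prs, gwas_name: str,
                  covars: pd.DataFrame, features: pd.DataFrame,
                  fdr: float = DEFAULT_FDR) -> EqtScoreResult:
    """Covariate-adjusted exon ~ PRS scan with per-gene FDR recalibration.

    ``prs`` may be a Series of per-sample scores or a samples x GWAS
    DataFrame, in which case ``gwas_name`` selects the column.  The scan
    runs on the entire sample (no case/control split) and diagnosis is
    deliberately not a covariate.
    """
    features = validate_feature_table(features)
    if isinstance(prs, pd.DataFrame):
        if gwas_name not in prs.columns:
            raise InputError(f"unknown GWAS name {gwas_name!r}; available: {list(prs.columns)}")
        prs = prs[gwas_name]
    shared = sorted(set(Y_exon.columns) & set(prs.index) & set(covars.index))
    if not shared:
        raise InputError("no overlapping samples between expression, PRS and covariates")
    Y = Y_exon[shared]
    exon_table = fit_matrix_association(Y, prs.loc[shared].to_numpy(),
                                        covars.loc[shared], predictor=gwas_name)
    gene_of = features.set_index("feature_id")["gene_id"]
    missing = [f for f in Y.index if f not in gene_of.index]
    if missing:
        raise InputError(f"expression features missing from annotation: {missing[:5]}")
    gene_table = multilevel_fdr(exon_table, gene_of)
    sig = gene_table[gene_table["fdr"] < fdr]
    return EqtScoreResult(
        gwas_name=gwas_name,
        exon_table=exon_table,
        gene_table=gene_table,
        significant_genes=sorted(sig["gene_id"]),
        significant_exons=sorted(sig["selected_feature_id"]),
    )


def assemble_joint_set(results: list[EqtScoreResult]) -> pd.DataFrame:
    """Union of significant genes across eQT-Scores with provenance flags.

    Returns a gene_id-sorted frame with one boolean column per GWAS and
    an ``n_gwas`` provenance count (every member has n_gwas >= 1).
    """
    if not results:
        raise InputError("need at least one eQT-Score result")
    names = [r.gwas_name for r in results]
    if len(set(names)) != len(names):
        raise InputError(f"duplicate GWAS names in joint set: {names}")
    union = sorted(set().union(*(set(r.significant_genes) for r in results)))
    out = pd.DataFrame({"gene_id": union})
    for r in results:
        out[r.gwas_name] = out["gene_id"].isin(set(r.significant_genes))
    out["n_gwas"] = out[names].sum(axis=1).astype(int)
    return out
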
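"""Covariate-adjusted linear-model engine and multiple-testing procedures.

This module is the statistical core shared by the differential-expression,
cis-eQTL and eQT-Score stages.  Every feature (gene, transcript or exon)
is fit with ordinary least squares::

    y = b0 + b1 * x + covariates @ gamma + e

where ``x`` is the predictor of interest (diagnosis, SNP dosage, or a
polygenic risk score) and the covariates reproduce a postmortem-brain
expression model: age, sex, pH, postmortem interval (PMI), RNA integrity
(RIN and RIN^2), suicide status, cause of death (CoD, 3-level categorical
dummy-coded against the "natural" reference), four ancestry dimensions
and one surrogate variable.  The reported two-sided p-value for ``x``
comes from the Student t distribution with ``n - p`` residual degrees of
freedom.

Multiple testing follows two procedures: plain Benjamini-Hochberg
(:func:`bh_fdr`) and the per-gene recalibration (:func:`multilevel_fdr`)
that keeps only each gene's smallest-p sub-feature before BH correction,
so genes with hundreds of exons do not inflate the correction burden.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, SingularDesignError

#: canonical covariate column order for the postmortem cohort model
COVARIATE_COLUMNS = [
    "age", "sex", "pH", "PMI", "RIN", "RIN2", "suicide", "CoD",
    "Dim1", "Dim2", "Dim3", "Dim4", "SV1",
]

_COD_REFERENCE = "natural"

ASSOCIATION_COLUMNS = [
    "feature_id", "predictor", "beta", "se", "t", "df", "p", "degenerate",
]


def covariate_design(covars: pd.DataFrame) -> pd.DataFrame:
    """Build the numeric covariate design (no intercept column).

    Categorical/object columns are dummy-coded; for cause of death the
    reference level is ``"natural"`` when present, otherwise the first
    sorted level.  ``RIN2`` is derived as ``RIN**2`` when absent.  Rows
    with any missing covariate are rejected.
    """
    if covars.isna().any().any():
        bad = covars.index[covars.isna().any(axis=1)].tolist()
        raise InputError(f"missing covariate values for samples: {bad[:5]}")
    covars = covars.copy()
    if "RIN" in covars.columns and "RIN2" not in covars.columns:
        covars["RIN2"] = covars["RIN"].astype(float) ** 2
    pieces = []
    for col in covars.columns:
        s = covars[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            ref = _COD_REFERENCE if _COD_REFERENCE in levels else levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                pieces.append(pd.Series((s.astype(str) == lev).astype(float),
                                        name=f"{col}[{lev}]"))
        else:
            pieces.append(s.astype(float))
    if not pieces:
        return pd.DataFrame(index=covars.index)
    return pd.concat(pieces, axis=1)


def _design_matrix(x: np.ndarray | None, covars: pd.DataFrame | None,
                   n: int) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if x is not None:
        cols.append(np.asarray(x, dtype=float))
        names.append("x")
    if covars is not None and covars.shape[1] > 0:
        design = covariate_design(covars)
        if len(design) != n:
            raise InputError("covariate rows do not match sample count")
        for c in design.columns:
            cols.append(design[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # small diagonal entries of R expose (near-)dependent columns
    _, r = np.linalg.qr(X)
    r = np.atleast_2d(r)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag <= tol).any():
        bad = [names[i] for i in np.flatnonzero(diag <= tol)]
        raise SingularDesignError(bad)


def _ols_matrix(Y: np.ndarray, X: np.ndarray, names: list[str],
                pred_idx: int = 1) -> pd.DataFrame:
    """Vectorised OLS of every row of Y on X; stats for column pred_idx.

    Identical to fitting each row separately: the normal equations are
    shared, only the right-hand sides differ.
    """
    n, p = X.shape
    if Y.shape[1] != n:
        raise InputError("expression columns do not match sample count")
    if n < p + 1:
        raise InputError(f"need at least {p + 1} samples for {p} model columns")
    _check_rank(X, names)
    XtX = X.T @ X
    XtXinv = np.linalg.inv(XtX)
    B = Y @ X @ XtXinv.T                      # m x p coefficients
    resid = Y - B @ X.T
    df = n - p
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    var_pred = XtXinv[pred_idx, pred_idx]
    se = np.sqrt(sigma2 * var_pred)
    beta = B[:, pred_idx].copy()

    degenerate = np.var(Y, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(np.isinf(t), 0.0, pvals)
    beta[degenerate] = 0.0
    se_out = se.copy()
    se_out[degenerate] = np.nan
    t = np.where(degenerate, 0.0, t)
    pvals = np.where(degenerate, 1.0, pvals)
    return pd.DataFrame({
        "beta": beta,
        "se": se_out,
        "t": t,
        "df": df,
        "p": np.clip(pvals, 0.0, 1.0),
        "degenerate": degenerate,
    })


def fit_feature_association(y, x, covars: pd.DataFrame | None = None,
                            feature_id: str = "feature",
                            predictor: str = "x") -> pd.Series:
    """OLS association of a single feature with a predictor.

    Returns a Series with beta/se/t/df/p for the predictor term.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise InputError("y and x lengths differ")
    X, names = _design_matrix(x, covars, len(y))
    row = _ols_matrix(y[None, :], X, names).iloc[0]
    out = pd.Series({"feature_id": feature_id, "predictor": predictor, **row})
    return out


def fit_matrix_association(Y: pd.DataFrame, x, covars: pd.DataFrame | None = None,
                           predictor: str = "x") -> pd.DataFrame:
    """Row-wise OLS association of a features x samples matrix with a predictor.

    Row ``i`` of the result equals :func:`fit_feature_association` on
    ``Y.iloc[i]``; rows keep the order of ``Y``.
    """
    x = np.asarray(x, dtype=float)
    if Y.shape[1] != len(x):
        raise InputError("expression columns and predictor length differ")
    X, names = _design_matrix(x, covars, len(x))
    table = _ols_matrix(Y.to_numpy(dtype=float), X, names)
    table.insert(0, "predictor", predictor)
    table.insert(0, "feature_id", list(Y.index))
    return table.reset_index(drop=True)


def residualize(Y: pd.DataFrame, covars: pd.DataFrame | None = None) -> pd.DataFrame:
    """Replace each feature by its OLS residuals on [intercept + covariates]."""
    n = Y.shape[1]
    X, names = _design_matrix(None, covars, n)
    _check_rank(X, names)
    XtXinv = np.linalg.inv(X.T @ X)
    vals = Y.to_numpy(dtype=float)
    resid = vals - (vals @ X) @ XtXinv @ X.T
    return pd.DataFrame(resid, index=Y.index, columns=Y.columns)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def multilevel_fdr(table: pd.DataFrame, feature_to_gene: Mapping | pd.Series) -> pd.DataFrame:
    """Per-gene FDR recalibration over lowest-p sub-features.

    For each gene the sub-feature (exon or transcript) with the smallest
    p-value is selected (ties broken by lexicographically smallest
    feature_id) and BH correction is re-run over the selected rows only.
    Returns one row per gene: gene_id, selected_feature_id, beta, p, fdr,
    sorted by gene_id.
    """
    if isinstance(feature_to_gene, pd.Series):
        mapping = feature_to_gene.to_dict()
    else:
        mapping = dict(feature_to_gene)
    feats = table["feature_id"]
    unmapped = [f for f in feats if f not in mapping]
    if unmapped:
        raise InputError(f"features without gene mapping: {unmapped[:10]}")
    work = table.copy()
    work["gene_id"] = [mapping[f] for f in feats]
    work = work.sort_values(["gene_id", "p", "feature_id"], kind="stable")
    sel = work.groupby("gene_id", sort=True).head(1).reset_index(drop=True)
    out = pd.DataFrame({
        "gene_id": sel["gene_id"],
        "selected_feature_id": sel["feature_id"],
        "beta": sel["beta"] if "beta" in sel else np.nan,
        "p": sel["p"],
    })
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)


def attach_fdr(table: pd.DataFrame, p_col: str = "p", out_col: str = "fdr") -> pd.DataFrame:
    """Return a copy of an association table with a BH FDR column."""
    out = table.copy()
    out[out_col] = bh_fdr(out[p_col].to_numpy())
    return out
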
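"""Enrichment analyses.

Three procedures:

* **MAF-matched permutation enrichment** of an eSNP set against a SNP
  annotation.  MAFs of the eSNP set and of the background are binned in
  increments of 0.05 on the 0-1 scale; each of the permutations draws a
  background sample matching the eSNP set's per-bin histogram exactly
  (without replacement within bins), so allele-frequency differences
  between the eSNP set and the background cannot masquerade as
  enrichment.  The odds ratio is observed overlap / mean null overlap
  and the empirical p-value uses add-one smoothing,
  ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
* **Three-way core-gene intersection** of eQTL genes, eQT-Score genes
  and a rare-variant gene list (exact string matching).
* **Hypergeometric gene-set over-representation** against a user
  background with BH FDR across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .errors import InputError

DEFAULT_N_PERM = 10_000
DEFAULT_BIN_WIDTH = 0.05


def bin_maf(maf, width: float = DEFAULT_BIN_WIDTH):
    """Half-open frequency bins [k*w, (k+1)*w) on [0, 1]; the top bin is
    closed so maf = 1.0 falls in the last bin.  Vectorized."""
    m = np.asarray(maf, dtype=float)
    if np.any((m < 0) | (m > 1) | np.isnan(m)):
        raise InputError("maf values must lie in [0, 1]")
    n_bins = int(round(1.0 / width))
    idx = np.floor(m / width).astype(int)
    idx = np.minimum(idx, n_bins - 1)
    return idx if idx.shape else int(idx)


def maf_matched_sample(background: pd.DataFrame, target_bin_counts: dict[int, int],
                       rng: np.random.Generator,
                       width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Sample background snp_ids matching per-bin counts exactly, without
    replacement within bins.  ``background`` needs snp_id + maf columns."""
    bins = bin_maf(background["maf"].to_numpy(), width)
    ids = background["snp_id"].to_numpy()
    out = []
    for b, need in sorted(target_bin_counts.items()):
        if need == 0:
            continue
        pool = ids[bins == b]
        if len(pool) < need:
            raise InputError(f"MAF bin {b} underfilled: need {need}, have {len(pool)}"
                             f" (deficit {need - len(pool)})")
        out.append(rng.choice(pool, size=need, replace=False))
    if not out:
        return np.array([], dtype=object)
    return np.concatenate(out)


@dataclass
class EnrichmentResult:
    """Observed vs MAF-matched null overlap of one eSNP set."""

    set_name: str
    annotation_name: str
    observed_overlap: int
    null_mean: float
    null_quantiles: dict[str, float]
    odds_ratio: float
    p_emp: float
    n_perm: int
    seed: int
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = self.p_emp < 0.05


def permutation_enrichment(esnps: pd.DataFrame, background: pd.DataFrame,
                           annotation, n_perm: int = DEFAULT_N_PERM,
                           width: float = DEFAULT_BIN_WIDTH, seed: int = 0,
                           set_name: str = "esnps", annotation_name: str = "annotation",
                           strict_exceedance: bool = False,
                           maf_matched: bool = True) -> EnrichmentResult:
    """MAF-bin-matched permutation test of eSNP/annotation overlap.

    ``esnps`` and ``background`` are frames with snp_id and maf columns;
    ``esnps`` must be a subset of ``background``.  ``annotation`` is a
    set of snp_ids.  ``maf_matched=False`` degrades to matching only the
    total count (the naive resampler, kept for demonstrating the bias
    the matched design removes).
    """
    esnp_ids = esnps["snp_id"].to_numpy()
    bg_ids = background["snp_id"].to_numpy()
    if len(set(esnp_ids)) != len(esnp_ids) or len(set(bg_ids)) != len(bg_ids):
        raise InputError("duplicate snp_ids in eSNP set or background")
    missing = set(esnp_ids) - set(bg_ids)
    if missing:
        raise InputError(f"eSNPs absent from background: {sorted(missing)[:5]}")
    annotation = set(annotation)
    rng = np.random.default_rng(seed)
    observed = int(len(set(esnp_ids) & annotation))

    member = np.fromiter((s in annotation for s in bg_ids), dtype=bool, count=len(bg_ids))
    if maf_matched:
        bins = bin_maf(background["maf"].to_numpy(), width)
        target = pd.Series(bin_maf(esnps["maf"].to_numpy(), width)).value_counts().to_dict()
        null = np.zeros(n_perm, dtype=int)
        for b, need in sorted(target.items()):
            pool = member[bins == b]
            if len(pool) < need:
                raise InputError(f"MAF bin {b} underfilled: need {need}, have {len(pool)}"
                                 f" (deficit {need - len(pool)})")
            # each row of a shuffled membership pool is a without-replacement draw
            tiled = np.tile(pool, (n_perm, 1))
            tiled = rng.permuted(tiled, axis=1)
            null += tiled[:, :need].sum(axis=1)
    else:
        need = len(esnp_ids)
        tiled = np.tile(member, (n_perm, 1))
        tiled = rng.permuted(tiled, axis=1)
        null = tiled[:, :need].sum(axis=1)

    if strict_exceedance:
        exceed = int((null > observed).sum())
    else:
        exceed = int((null >= observed).sum())
    p_emp = (1 + exceed) / (1 + n_perm)
    null_mean = float(null.mean())
    if null_mean > 0:
        odds_ratio = observed / null_mean
    else:
        odds_ratio = float("inf") if observed > 0 else 1.0
    qs = np.quantile(null, [0.025, 0.25, 0.5, 0.75, 0.975])
    return EnrichmentResult(
        set_name=set_name, annotation_name=annotation_name,
        observed_overlap=observed, null_mean=null_mean,
        null_quantiles={"q2.5": float(qs[0]), "q25": float(qs[1]), "q50": float(qs[2]),
                        "q75": float(qs[3]), "q97.5": float(qs[4])},
        odds_ratio=float(odds_ratio), p_emp=float(p_emp), n_perm=n_perm, seed=seed,
    )


def intersect_core_genes(eqtl_genes, eqtscore_genes, rare_genes) -> list[str]:
    """Genes present in all three evidence categories (exact ids), sorted."""
    return sorted(set(eqtl_genes) & set(eqtscore_genes) & set(rare_genes))


def hypergeometric_enrichment(query, gene_sets: dict, background,
                              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    ``query`` must be contained in ``background``; sets are intersected
    with the background before testing.  Fold enrichment is
    (overlap/|query|) / (|set n bg|/|background|).
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise InputError(f"query genes absent from background: {sorted(stray)[:10]}")
    N, n_draw = len(background), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw)) if K else 1.0
        fold = (k / n_draw) / (K / N) if (K and n_draw) else 0.0
        rows.append((name, k, K, n_draw, N, fold, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "query_size",
                                      "background_size", "fold_enrichment", "p"])
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["fdr"] <= fdr_threshold
    else:
        out["fdr"] = []
        out["significant"] = []
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
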
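"""Cell-type enrichment by top-quantile cell scoring.

Each cell is scored by the mean (normalised) expression of a gene set;
the top 25% of cells under the core-gene score are compared with the top
25% under the background-gene score, and a one-sided Fisher's exact test
asks, per cell type, whether the type is over-represented among the
core-top cells relative to the background-top cells.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr
from .containers import CellMatrix
from .errors import InputError

DEFAULT_FRACTION = 0.25


def cell_scores(cells: CellMatrix, genes) -> tuple[pd.Series, dict]:
    """Per-cell mean expression over the detected members of a gene set.

    Returns (scores, info) where info reports requested vs detected gene
    counts — requested genes missing from the matrix are simply dropped.
    """
    requested = list(genes)
    detected = [g for g in requested if g in cells.expr.columns]
    if not detected:
        raise InputError("none of the requested genes are present in the cell matrix")
    scores = cells.expr[detected].mean(axis=1)
    scores.name = "score"
    return scores, {"n_requested": len(requested), "n_detected": len(detected)}


def top_fraction_cells(scores: pd.Series, frac: float = DEFAULT_FRACTION) -> list[str]:
    """Ids of the ceil(frac * n) highest-scoring cells.

    Ties at the cutoff are broken by ascending cell id so the set size
    is exact and deterministic.
    """
    if len(scores) == 0:
        raise InputError("empty score vector")
    if not 0 < frac <= 1:
        raise InputError("frac must lie in (0, 1]")
    k = math.ceil(frac * len(scores))
    order = pd.DataFrame({"score": scores.to_numpy(), "cell": scores.index.to_numpy()})
    order = order.sort_values(["score", "cell"], ascending=[False, True], kind="stable")
    return order["cell"].head(k).tolist()


def fisher_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on [[a, b], [c, d]].

    Returns (odds_ratio, p).  The p-value is the hypergeometric upper
    tail P(X >= a) with population a+b+c+d, successes a+c, draws a+b.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise InputError("contingency counts must be non-negative")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def celltype_enrichment(cells: CellMatrix, core, background,
                        frac: float = DEFAULT_FRACTION,
                        comparator: str = "background_top",
                        p_threshold: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-cell-type Fisher enrichment of core-top vs background-top cells.

    ``comparator="background_top"`` (default) contrasts the top-``frac``
    cells under the core score with the top-``frac`` cells under the
    background score; ``comparator="all_cells"`` contrasts them with the
    full cell population instead.
    """
    core, background = list(core), list(background)
    if not set(core) <= set(background):
        warnings.warn("core gene set is not contained in the background set")
    core_scores, core_info = cell_scores(cells, core)
    top_core = top_fraction_cells(core_scores, frac)
    if comparator == "background_top":
        bg_scores, bg_info = cell_scores(cells, background)
        comp = top_fraction_cells(bg_scores, frac)
    elif comparator == "all_cells":
        comp = cells.cell_ids
        _, bg_info = cell_scores(cells, background)
    else:
        raise InputError(f"unknown comparator {comparator!r}")
    lab = cells.labels
    lab_core = lab.loc[top_core]
    lab_comp = lab.loc[comp]
    rows = []
    for ct in cells.cell_types:
        a = int((lab_core == ct).sum())
        b = len(top_core) - a
        c = int((lab_comp == ct).sum())
        d = len(comp) - c
        odds, p = fisher_greater(a, b, c, d)
        rows.append((ct, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["cell_type", "a", "b", "c", "d", "odds_ratio", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p"] < p_threshold
    info = {"core": core_info, "background": bg_info,
            "n_top_core": len(top_core), "n_comparator": len(comp)}
    return out, info
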
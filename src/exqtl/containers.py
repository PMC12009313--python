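"""In-memory containers shared by the pipeline stages.

Conventions used throughout the package:

* **GenotypeMatrix** — additive dosages (alt-allele counts, possibly
  fractional after imputation or when read from a DS field) as a
  samples x SNPs :class:`pandas.DataFrame`, plus a per-SNP metadata frame
  indexed by ``snp_id`` with columns ``chrom, pos, ref, alt, maf``.
  Positions are 1-based.
* **ExpressionMatrix** — a features x samples ``DataFrame`` (rows indexed
  by ``feature_id``).
* **FeatureTable** — annotation ``DataFrame`` with columns
  ``feature_id, gene_id, transcript_id, level, chrom, start, end`` where
  ``level`` is one of ``gene | transcript | exon`` and coordinates are
  1-based inclusive.
* **CellMatrix** — cells x genes expression with one cell-type label per
  cell; values are assumed already normalised/log-scale and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

FEATURE_COLUMNS = ["feature_id", "gene_id", "transcript_id", "level", "chrom", "start", "end"]
SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "maf"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata."""

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self):
        if list(self.dosages.columns) != list(self.snps.index):
            raise InputError("dosage columns and SNP metadata index disagree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> "GenotypeMatrix":
        """Return a copy with missing dosages mean-imputed per SNP."""
        d = self.dosages.astype(float)
        if d.isna().any().any():
            d = d.fillna(d.mean(axis=0))
        return GenotypeMatrix(dosages=d, snps=self.snps.copy())

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(dosages=self.dosages.loc[list(sample_ids)], snps=self.snps)


@dataclass
class CellMatrix:
    """Cells x genes expression with one cell-type label per cell."""

    expr: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if not self.expr.index.equals(self.labels.index):
            raise InputError("cell ids of expression matrix and labels differ")
        if len(self.labels) == 0:
            raise InputError("empty cell matrix")
        vals = self.expr.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise InputError("cell expression values must be finite and non-negative")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.labels.unique())


def validate_feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation frame contract and return it unchanged."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise InputError(f"feature table lacks columns: {missing}")
    if features["feature_id"].duplicated().any():
        dupes = features.loc[features["feature_id"].duplicated(), "feature_id"].tolist()
        raise InputError(f"duplicate feature ids: {dupes[:5]}")
    bad = features["start"] > features["end"]
    if bad.any():
        raise InputError("feature start > end for " + str(features.loc[bad, "feature_id"].tolist()[:5]))
    return features


def feature_level(features: pd.DataFrame, level: str) -> pd.DataFrame:
    sub = features[features["level"] == level]
    if sub.empty:
        raise InputError(f"no features at level '{level}'")
    return sub
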
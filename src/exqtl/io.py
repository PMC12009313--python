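"""Readers and writers for the standard formats the pipeline consumes.

Coordinate conventions: VCF and the annotation TSV are 1-based
inclusive; BED is 0-based half-open and :func:`snp_in_intervals` is the
single place where the two are reconciled (a SNP at 1-based position
``pos`` is tested as ``pos - 1`` against [start, end)).

All tabular outputs are TSV with a header line and stable column order;
floats are written with 6 significant digits, p-values in scientific
notation, so identical runs are byte-identical.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CellMatrix, GenotypeMatrix, FEATURE_COLUMNS
from .errors import InputError

_P_COLUMNS = {"p", "fdr", "p_emp"}


def _fmt_value(v, scientific: bool = False) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return f"{v:.6e}" if scientific else f"{v:.6g}"
    return str(v)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a frame as TSV with the package's float conventions."""
    df = df.reset_index() if index else df
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        sci = [c in _P_COLUMNS for c in df.columns]
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt_value(v, s) for v, s in zip(row, sci)) + "\n")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


# ---------------------------------------------------------------- genotypes

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with GT fields (hard calls) per sample.

    Fractional dosages are rounded to the nearest hard call for GT and
    written exactly in a DS field; missing dosages become "./.".
    """
    dos = geno.dosages
    has_fractional = bool(np.any(dos.to_numpy() % 1 != 0))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_fractional:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:DS" if has_fractional else "GT"
        for sid, meta in geno.snps.iterrows():
            calls = []
            for v in dos[sid]:
                if pd.isna(v):
                    calls.append("./." + (":." if has_fractional else ""))
                else:
                    gt = gt_map[int(round(min(max(v, 0), 2)))]
                    calls.append(f"{gt}:{v:g}" if has_fractional else gt)
            fh.write(f"{meta['chrom']}\t{meta['pos']}\t{sid}\t{meta['ref']}\t{meta['alt']}"
                     f"\t.\t.\t.\t{fmt}\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF; DS dosages are honored over GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, ids = [], [], []
    for i, var in enumerate(vcf):
        sid = var.ID or f"snp{i + 1}"
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = ds.astype(float).ravel()
            vals = np.where(np.isfinite(vals), vals, np.nan)
        else:
            vals = np.empty(len(samples))
            for j, g in enumerate(var.genotypes):
                alleles = [a for a in g[:-1]]
                if len(alleles) != 2:
                    raise InputError(f"mixed ploidy at {sid}")
                if any(a < 0 for a in alleles):
                    vals[j] = np.nan
                else:
                    vals[j] = sum(1 for a in alleles if a > 0)
        rows.append(vals)
        ids.append(sid)
        alt = var.ALT[0] if var.ALT else "."
        meta.append((var.CHROM, var.POS, var.REF, alt))
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"],
                        index=pd.Index(ids, name="snp_id"))
    filled = dosages.fillna(dosages.mean(axis=0))
    f = filled.sum(axis=0) / (2 * len(samples))
    snps["maf"] = np.minimum(f, 1 - f)
    snps["chrom"] = snps["chrom"].astype(str)
    return GenotypeMatrix(dosages=dosages, snps=snps)


def write_dosage_tsv(geno: GenotypeMatrix, dosage_path, meta_path=None) -> None:
    write_tsv(geno.dosages.T, dosage_path, index=True)
    if meta_path:
        write_tsv(geno.snps, meta_path, index=True)


def read_dosage_tsv(dosage_path, meta_path=None) -> GenotypeMatrix:
    dos = read_tsv(dosage_path, index_col=0).T.astype(float)
    dos.index.name = None
    if meta_path and os.path.exists(str(meta_path)):
        snps = read_tsv(meta_path, index_col=0)
        snps["chrom"] = snps["chrom"].astype(str)
    else:
        f = dos.fillna(dos.mean(axis=0)).sum(axis=0) / (2 * len(dos))
        snps = pd.DataFrame({"chrom": "1", "pos": 0, "ref": "N", "alt": "N",
                             "maf": np.minimum(f, 1 - f)}, index=dos.columns)
        snps.index.name = "snp_id"
    return GenotypeMatrix(dosages=dos, snps=snps)


def read_genotypes(path, meta_path=None) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, else dosage TSV."""
    p = str(path)
    if not os.path.exists(p):
        raise InputError(f"no such file: {p}")
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_dosage_tsv(p, meta_path)


# ------------------------------------------------------------- annotations

def write_expression(Y: pd.DataFrame, path) -> None:
    write_tsv(Y, path, index=True)


def read_expression(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def write_annotation(features: pd.DataFrame, path) -> None:
    write_tsv(features[FEATURE_COLUMNS], path)


def read_annotation(path) -> pd.DataFrame:
    feats = read_tsv(path)
    feats["chrom"] = feats["chrom"].astype(str)
    feats["transcript_id"] = feats["transcript_id"].fillna("")
    return feats


def write_covariates(cov: pd.DataFrame, path) -> None:
    write_tsv(cov, path, index=True)


def read_covariates(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def read_annotation_bed(path) -> pd.DataFrame:
    """BED intervals (0-based half-open) as a chrom/start/end frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise InputError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def snp_in_intervals(snps: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Membership of 1-based SNP positions in 0-based half-open intervals."""
    result = pd.Series(False, index=snps.index)
    for chrom, sub in intervals.groupby("chrom"):
        mask = snps["chrom"].astype(str) == str(chrom)
        if not mask.any():
            continue
        pos0 = snps.loc[mask, "pos"].to_numpy() - 1   # the one conversion point
        hit = np.zeros(mask.sum(), dtype=bool)
        for iv in sub.itertuples(index=False):
            hit |= (pos0 >= iv.start) & (pos0 < iv.end)
        result.loc[mask] = hit
    return result


# ------------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, list[str]]:
    """Named gene sets; duplicate genes deduplicated (first occurrence),
    empty sets dropped, duplicate set names rejected."""
    import warnings

    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: GMT needs name, description, genes")
            name = parts[0]
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                warnings.warn(f"{path}:{lineno}: dropping empty set {name!r}")
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        genes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    if genes and genes[0].lower() in {"gene_id", "gene"}:
        genes = genes[1:]
    return genes


def write_gene_list(genes, path, header: str = "gene_id") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for g in genes:
            fh.write(str(g) + "\n")


# ------------------------------------------------------------------- GWAS

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "A1", "A2", "beta", "p"]


def write_gwas(gwas: pd.DataFrame, path) -> None:
    cols = [c for c in ["snp_id", "chrom", "pos", "A1", "A2", "beta", "se", "p"]
            if c in gwas.columns]
    out = gwas[cols].rename(columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                                     "beta": "BETA", "se": "SE", "p": "P"})
    write_tsv(out, path)


def read_gwas(path) -> pd.DataFrame:
    """GWAS summary TSV; an OR column is accepted and log-transformed."""
    raw = read_tsv(path)
    cols = {c.upper(): c for c in raw.columns}
    need = ["SNP", "CHR", "BP", "A1", "A2", "P"]
    missing = [c for c in need if c not in cols]
    if missing:
        raise InputError(f"GWAS file lacks columns: {missing}")
    out = pd.DataFrame({
        "snp_id": raw[cols["SNP"]],
        "chrom": raw[cols["CHR"]].astype(str),
        "pos": raw[cols["BP"]],
        "A1": raw[cols["A1"]],
        "A2": raw[cols["A2"]],
        "p": raw[cols["P"]].astype(float),
    })
    if "BETA" in cols:
        out["beta"] = raw[cols["BETA"]].astype(float)
    elif "OR" in cols:
        out["beta"] = np.log(raw[cols["OR"]].astype(float))
    else:
        raise InputError("GWAS file needs a BETA or OR column")
    if "SE" in cols:
        out["se"] = raw[cols["SE"]].astype(float)
    return out


# ------------------------------------------------------------ single cell

def write_cells(cells: CellMatrix, prefix) -> None:
    """MatrixMarket MTX (genes x cells) + features/barcodes/labels TSV."""
    prefix = str(prefix)
    mat = sparse.csr_matrix(cells.expr.to_numpy().T)
    spio.mmwrite(prefix + ".mtx", mat)
    with open(prefix + ".features.tsv", "w") as fh:
        for g in cells.gene_ids:
            fh.write(g + "\n")
    with open(prefix + ".barcodes.tsv", "w") as fh:
        for c in cells.cell_ids:
            fh.write(c + "\n")
    with open(prefix + ".labels.tsv", "w") as fh:
        fh.write("barcode\tcell_type\n")
        for c in cells.cell_ids:
            fh.write(f"{c}\t{cells.labels[c]}\n")


def read_cells(prefix) -> CellMatrix:
    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray().T
    with open(prefix + ".features.tsv") as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    with open(prefix + ".barcodes.tsv") as fh:
        cells = [ln.strip() for ln in fh if ln.strip()]
    labels = read_tsv(prefix + ".labels.tsv", index_col=0)["cell_type"]
    expr = pd.DataFrame(mat, index=pd.Index(cells, name="cell_id"), columns=genes)
    return CellMatrix(expr=expr, labels=labels.loc[cells])
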
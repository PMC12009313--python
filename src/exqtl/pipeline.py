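"""Pipeline orchestration: simulate -> de -> eqtl -> prs -> eqtscore ->
core-genes -> enrichment -> celltype, with a machine-readable manifest.

Thresholds default to the analysis constants of the underlying study
design: DE FDR < 0.1, cis window 1 Mb, eQTL MAF > 0.05 and FDR < 0.05,
PRS p <= 0.01, 10 000 enrichment permutations with 0.05-wide MAF bins,
pathway FDR <= 0.05, top-25% cell scoring with Fisher p < 0.05.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import __version__, io as eio
from .association import attach_fdr, fit_matrix_association, multilevel_fdr
from .celltype import celltype_enrichment
from .enrichment import (hypergeometric_enrichment, intersect_core_genes,
                         permutation_enrichment)
from .eqt_score import assemble_joint_set, run_eqt_score
from .eqtl import run_cis_eqtl
from .errors import ConfigError, DependencyError
from .prs import prs_table
from .simulate import (SimConfig, child_rng, simulate_cells, simulate_cohort,
                       simulate_pathways)

log = logging.getLogger("exqtl")

STAGES = ["simulate", "de", "eqtl", "prs", "eqtscore", "core_genes",
          "enrich_snps", "enrich_pathways", "celltype"]

_DEPENDS = {
    "de": ["simulate"],
    "eqtl": ["simulate"],
    "prs": ["simulate"],
    "eqtscore": ["simulate", "prs"],
    "core_genes": ["eqtl", "eqtscore"],
    "enrich_snps": ["eqtl"],
    "enrich_pathways": ["core_genes"],
    "celltype": ["simulate", "core_genes"],
}


@dataclass
class RunConfig:
    """Run-level settings; threshold defaults follow the study design."""

    seed: int = 0
    out_dir: str = "exqtl_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: SimConfig = field(default_factory=SimConfig)
    de_fdr: float = 0.1
    eqtl_fdr: float = 0.05
    eqtl_maf: float = 0.05
    cis_window: int = 1_000_000
    prs_p: float = 0.01
    prs_clump: bool = True
    prs_standardize: bool = False
    enrich_nperm: int = 10_000
    enrich_bin: float = 0.05
    pathway_fdr: float = 0.05
    celltype_frac: float = 0.25
    celltype_p: float = 0.05

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        # the simulation inherits the run seed
        if self.sim.seed != self.seed:
            self.sim = SimConfig(**{**asdict(self.sim), "seed": self.seed})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", {})
        for key in ("maf_range", "exons_per_gene", "n_transcripts_per_gene",
                    "pathway_size", "gwas_names", "cell_type_labels", "cell_type_props"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        cfg = cls(**raw)
        if sim:
            cfg.sim = SimConfig(**{**asdict(cfg.sim), **sim})
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Executes stages in dependency order and records a manifest."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = config.out_dir
        os.makedirs(self.out, exist_ok=True)
        self.completed: dict[str, list[str]] = {}
        self.state: dict[str, object] = {}

    # -- helpers ----------------------------------------------------------
    def _path(self, name: str) -> str:
        return os.path.join(self.out, name)

    def _require(self, stage: str) -> None:
        for dep in _DEPENDS.get(stage, []):
            if dep not in self.completed:
                raise DependencyError(f"stage '{stage}' requires stage '{dep}' to run first")

    def _record(self, stage: str, paths: list[str]) -> None:
        self.completed[stage] = [os.path.basename(p) for p in paths]

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg
        log.info("[simulate] generating cohort (seed=%d)", cfg.seed)
        bundle = simulate_cohort(cfg.sim)
        self.state["bundle"] = bundle
        gene_ids = sorted(bundle.features.loc[bundle.features["level"] == "gene", "feature_id"])
        cells = simulate_cells(cfg.sim.n_cells, cfg.sim.cell_type_labels,
                               cfg.sim.cell_type_props, gene_ids,
                               bias_genes=bundle.truth.core_genes,
                               bias_target=cfg.sim.celltype_bias_target,
                               bias_factor=cfg.sim.celltype_bias_factor,
                               seed=cfg.seed)
        self.state["cells"] = cells
        pathways = simulate_pathways(gene_ids, bundle.truth.core_genes,
                                     cfg.sim.n_pathways, cfg.sim.pathway_size,
                                     seed=cfg.seed)
        self.state["pathways"] = pathways
        # a synthetic SNP annotation: intervals covering ~30% of SNP positions
        rng = child_rng(cfg.seed, "annotation-bed")
        snps = bundle.genotypes.snps
        hit = rng.random(len(snps)) < 0.3
        iv = pd.DataFrame({"chrom": snps.loc[hit, "chrom"],
                           "start": snps.loc[hit, "pos"] - 1,
                           "end": snps.loc[hit, "pos"]})
        self.state["annotation_bed"] = iv

        paths = []
        def w(name, fn):
            p = self._path(name)
            fn(p)
            paths.append(p)
        w("genotypes.vcf", lambda p: eio.write_vcf(bundle.genotypes, p))
        w("expression_exon.tsv", lambda p: eio.write_expression(bundle.exon_expr, p))
        w("expression_transcript.tsv", lambda p: eio.write_expression(bundle.transcript_expr, p))
        w("expression_gene.tsv", lambda p: eio.write_expression(bundle.gene_expr, p))
        w("annotation.tsv", lambda p: eio.write_annotation(bundle.features, p))
        w("covariates.tsv", lambda p: eio.write_covariates(bundle.covariates, p))
        w("diagnosis.tsv", lambda p: eio.write_tsv(bundle.diagnosis.to_frame(), p, index=True))
        for gname, tab in bundle.gwas.items():
            w(f"gwas_{gname}.tsv", lambda p, t=tab: eio.write_gwas(t, p))
        w("rare_genes.tsv", lambda p: eio.write_gene_list(bundle.rare_genes, p))
        w("pathways.gmt", lambda p: eio.write_gmt(pathways, p))
        w("annotation_snps.bed", lambda p: eio.write_bed(iv, p))
        w("cells", lambda p: eio.write_cells(cells, p))
        paths[-1:] = [self._path("cells" + ext)
                      for ext in (".mtx", ".features.tsv", ".barcodes.tsv", ".labels.tsv")]
        w("truth_eqtl.tsv", lambda p: eio.write_tsv(bundle.truth.eqtl, p))
        w("truth_de.tsv", lambda p: eio.write_tsv(bundle.truth.de, p))
        w("truth_prs.tsv", lambda p: eio.write_tsv(bundle.truth.prs, p))
        w("truth_core_genes.tsv", lambda p: eio.write_gene_list(bundle.truth.core_genes, p))
        self._record("simulate", paths)

    def stage_de(self) -> None:
        self._require("de")
        cfg, bundle = self.cfg, self.state["bundle"]
        log.info("[de] differential expression at three levels")
        diag = bundle.diagnosis.to_numpy()
        gene_of = bundle.features.set_index("feature_id")["gene_id"]
        results = {}
        paths = []
        for level, Y in (("gene", bundle.gene_expr), ("transcript", bundle.transcript_expr),
                         ("exon", bundle.exon_expr)):
            tab = fit_matrix_association(Y, diag, bundle.covariates, predictor="diagnosis")
            if level == "gene":
                tab = attach_fdr(tab)
                gl = tab.rename(columns={"feature_id": "gene_id"})[["gene_id", "beta", "p", "fdr"]]
                gl.insert(1, "selected_feature_id", gl["gene_id"])
            else:
                gl = multilevel_fdr(tab, gene_of)
            results[level] = gl
            p1 = self._path(f"de_{level}_features.tsv")
            eio.write_tsv(attach_fdr(tab), p1)
            p2 = self._path(f"de_{level}_genes.tsv")
            eio.write_tsv(gl, p2)
            paths += [p1, p2]
        self.state["de"] = results
        self.state["de_genes"] = {
            lvl: sorted(gl.loc[gl["fdr"] < cfg.de_fdr, "gene_id"]) for lvl, gl in results.items()
        }
        self._record("de", paths)

    def stage_eqtl(self) -> None:
        self._require("eqtl")
        cfg, bundle = self.cfg, self.state["bundle"]
        results = {}
        paths = []
        for level, Y in (("gene", bundle.gene_expr), ("transcript", bundle.transcript_expr),
                         ("exon", bundle.exon_expr)):
            log.info("[eqtl] cis scan at %s level", level)
            res = run_cis_eqtl(bundle.genotypes, Y, bundle.covariates, bundle.features,
                               window=cfg.cis_window, maf_min=cfg.eqtl_maf,
                               fdr_threshold=cfg.eqtl_fdr)
            results[level] = res
            p1 = self._path(f"eqtl_{level}_pairs.tsv")
            eio.write_tsv(res.pairs, p1)
            p2 = self._path(f"eqtl_{level}_genes.tsv")
            eio.write_gene_list(res.eqtl_genes, p2)
            paths += [p1, p2]
        self.state["eqtl"] = results
        self._record("eqtl", paths)

    def stage_prs(self) -> None:
        self._require("prs")
        cfg, bundle = self.cfg, self.state["bundle"]
        log.info("[prs] clumping+thresholding scores for %d GWASs", len(bundle.gwas))
        table = prs_table(bundle.genotypes, bundle.gwas, p_threshold=cfg.prs_p,
                          clump=cfg.prs_clump, standardize=cfg.prs_standardize)
        self.state["prs"] = table
        p = self._path("prs.tsv")
        eio.write_tsv(table, p, index=True)
        self._record("prs", [p])

    def stage_eqtscore(self) -> None:
        self._require("eqtscore")
        cfg, bundle = self.cfg, self.state["bundle"]
        prs = self.state["prs"]
        results = []
        control = None
        paths = []
        for gname in prs.columns:
            log.info("[eqtscore] %s", gname)
            res = run_eqt_score(bundle.exon_expr, prs, gname, bundle.covariates,
                                bundle.features, fdr=cfg.de_fdr)
            p1 = self._path(f"eqtscore_{gname}_exons.tsv")
            eio.write_tsv(res.exon_table, p1)
            p2 = self._path(f"eqtscore_{gname}_genes.tsv")
            eio.write_tsv(res.gene_table, p2)
            paths += [p1, p2]
            if gname == cfg.sim.negative_control:
                control = res
            else:
                results.append(res)
        joint = assemble_joint_set(results)
        self.state["eqtscore"] = results
        self.state["eqtscore_control"] = control
        self.state["joint_set"] = joint
        p3 = self._path("eqtscore_joint_genes.tsv")
        eio.write_tsv(joint, p3)
        summary = {r.gwas_name: {"genes": len(r.significant_genes),
                                 "exons": len(r.significant_exons)} for r in results}
        if control is not None:
            summary[control.gwas_name] = {"genes": len(control.significant_genes),
                                          "exons": len(control.significant_exons),
                                          "negative_control": True}
        p4 = self._path("eqtscore_summary.json")
        with open(p4, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        self._record("eqtscore", paths + [p3, p4])

    def stage_core_genes(self) -> None:
        self._require("core_genes")
        bundle = self.state["bundle"]
        eqtl_genes = self.state["eqtl"]["exon"].eqtl_genes
        joint_genes = list(self.state["joint_set"]["gene_id"])
        core = intersect_core_genes(eqtl_genes, joint_genes, bundle.rare_genes)
        log.info("[core_genes] %d core genes", len(core))
        self.state["core_genes"] = core
        p = self._path("core_genes.tsv")
        eio.write_gene_list(core, p)
        self._record("core_genes", [p])

    def stage_enrich_snps(self) -> None:
        self._require("enrich_snps")
        cfg, bundle = self.cfg, self.state["bundle"]
        res = self.state["eqtl"]["exon"]
        pairs = res.pairs
        tested = sorted(pairs["snp_id"].unique())
        snps = bundle.genotypes.snps
        background = pd.DataFrame({"snp_id": tested,
                                   "maf": snps.loc[tested, "maf"].to_numpy()})
        esnp_ids = sorted(pairs.loc[pairs["significant"], "snp_id"].unique())
        esnps = background[background["snp_id"].isin(esnp_ids)].reset_index(drop=True)
        member = eio.snp_in_intervals(snps.loc[tested], self.state["annotation_bed"])
        annotation = set(member.index[member])
        log.info("[enrich_snps] %d eSNPs vs %d annotated of %d background",
                 len(esnps), len(annotation), len(background))
        result = permutation_enrichment(esnps, background, annotation,
                                        n_perm=cfg.enrich_nperm, width=cfg.enrich_bin,
                                        seed=cfg.seed, set_name="exon_esnps")
        self.state["enrich_snps"] = result
        p = self._path("enrich_snps.json")
        with open(p, "w") as fh:
            json.dump({k: v for k, v in result.__dict__.items()}, fh,
                      indent=2, sort_keys=True, default=float)
        self._record("enrich_snps", [p])

    def stage_enrich_pathways(self) -> None:
        self._require("enrich_pathways")
        cfg, bundle = self.cfg, self.state["bundle"]
        background = sorted(bundle.features.loc[bundle.features["level"] == "gene",
                                                "feature_id"])
        table = hypergeometric_enrichment(self.state["core_genes"],
                                          self.state["pathways"], background,
                                          fdr_threshold=cfg.pathway_fdr)
        log.info("[enrich_pathways] %d significant pathways", int(table["significant"].sum()))
        self.state["enrich_pathways"] = table
        p = self._path("enrich_pathways.tsv")
        eio.write_tsv(table, p)
        self._record("enrich_pathways", [p])

    def stage_celltype(self) -> None:
        self._require("celltype")
        cfg = self.cfg
        cells = self.state["cells"]
        background = cells.gene_ids
        table, info = celltype_enrichment(cells, self.state["core_genes"], background,
                                          frac=cfg.celltype_frac, p_threshold=cfg.celltype_p)
        log.info("[celltype] top type: %s", table.sort_values("p").iloc[0]["cell_type"])
        self.state["celltype"] = (table, info)
        p = self._path("celltype_enrichment.tsv")
        eio.write_tsv(table, p)
        self._record("celltype", [p])

    # -- driver -----------------------------------------------------------
    def run(self) -> str:
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                log.error("stage '%s' failed; completed outputs preserved in %s",
                          stage, self.out)
                raise
        manifest = {
            "version": __version__,
            "seed": self.cfg.seed,
            "parameters": {f.name: getattr(self.cfg, f.name)
                           for f in fields(self.cfg)
                           if f.name not in ("sim", "stages", "out_dir")},
            "stage_order": [s for s in STAGES if s in self.cfg.stages],
            "sim": asdict(self.cfg.sim),
            "stages": {s: {name: _sha256(self._path(name)) for name in names}
                       for s, names in self.completed.items()},
        }
        mpath = self._path("manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return self.out


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Run all configured stages; returns the PipelineRun with state."""
    run = PipelineRun(config)
    run.run()
    return run
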
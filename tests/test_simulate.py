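"""Synthetic cohort generator: determinism, planted truth, sampling laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exqtl.errors import ConfigError
from exqtl.simulate import (SimConfig, simulate_annotation, simulate_cells,
                            simulate_cohort, simulate_genotypes, validate_truth)
from tests.conftest import SMALL


# ------------------------------------------------------------- genotypes

def test_genotype_mean_dosage_at_half_frequency():
    g = simulate_genotypes(10_000, 1, maf_range=(0.5, 0.5), seed=11)
    se = np.sqrt(2 * 0.25 / 10_000)
    assert abs(g.dosages.to_numpy().mean() - 1.0) <= 3 * se


def test_genotype_determinism():
    a = simulate_genotypes(50, 20, seed=5)
    b = simulate_genotypes(50, 20, seed=5)
    pd.testing.assert_frame_equal(a.dosages, b.dosages)
    pd.testing.assert_frame_equal(a.snps, b.snps)


def test_realized_frequency_matches_binomial_sampling():
    """Realized allele frequency stays within 3 binomial SE in >=99/100 seeds."""
    se = 3 * np.sqrt(0.3 * 0.7 / 4000)
    ok = sum(
        abs(simulate_genotypes(2000, 1, maf_range=(0.3, 0.3), seed=s)
            .dosages.to_numpy().sum() / 4000 - 0.3) <= se
        for s in range(100)
    )
    assert ok >= 99


def test_genotype_invalid_config_rejected():
    with pytest.raises(ConfigError):
        simulate_genotypes(1, 5, seed=0)
    with pytest.raises(ConfigError):
        simulate_genotypes(10, 5, maf_range=(0.0, 0.6), seed=0)


def test_snps_avoid_strand_ambiguous_pairs():
    g = simulate_genotypes(10, 200, seed=7)
    pairs = set(map(frozenset, zip(g.snps["ref"], g.snps["alt"])))
    assert frozenset("AT") not in pairs and frozenset("CG") not in pairs


# ------------------------------------------------------------ annotation

def test_annotation_exon_containment_and_counts():
    feats = simulate_annotation(1, exons_per_gene=(3, 3), seed=1)
    genes = feats[feats["level"] == "gene"]
    exons = feats[feats["level"] == "exon"]
    assert len(genes) == 1 and len(exons) == 3
    g = genes.iloc[0]
    assert ((exons["start"] >= g["start"]) & (exons["end"] <= g["end"])).all()


def test_annotation_ids_unique_and_graph_is_forest():
    feats = simulate_annotation(25, seed=9)
    assert feats["feature_id"].is_unique
    exons = feats[feats["level"] == "exon"]
    tx = feats[feats["level"] == "transcript"].set_index("feature_id")
    genes = set(feats.loc[feats["level"] == "gene", "feature_id"])
    # every exon points to one transcript which points to the same gene (root)
    for row in exons.itertuples(index=False):
        assert row.gene_id in genes
        assert tx.loc[row.transcript_id, "gene_id"] == row.gene_id
    # genes do not overlap
    g = feats[feats["level"] == "gene"].sort_values("start")
    assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()


# ---------------------------------------------------------------- cohort

def test_cohort_determinism(small_bundle):
    again = simulate_cohort(SMALL)
    pd.testing.assert_frame_equal(small_bundle.exon_expr, again.exon_expr)
    pd.testing.assert_frame_equal(small_bundle.genotypes.dosages, again.genotypes.dosages)
    pd.testing.assert_series_equal(small_bundle.diagnosis, again.diagnosis)
    pd.testing.assert_frame_equal(small_bundle.gwas["SCZ"], again.gwas["SCZ"])


def test_truth_ids_resolve(small_bundle):
    validate_truth(small_bundle)


def test_noise_free_null_cohort_is_constant():
    cfg = SimConfig(seed=4, n_samples=20, n_snps=10, n_genes=4, noise_sd=0.0,
                    covariate_effect_sd=0.0, frac_eqtl_exons=0, frac_de_exons=0,
                    frac_prs_exons=0, n_core_genes=0, n_rare_genes=0,
                    n_causal_prs_snps=2, n_cells=10)
    b = simulate_cohort(cfg)
    assert (b.exon_expr.std(axis=1) < 1e-12).all()


def test_single_exon_effect_dilutes_by_exon_count():
    """With zero noise, the gene-level slope is exactly beta / n_exons."""
    cfg = SimConfig(seed=8, n_samples=60, n_snps=30, n_genes=5,
                    exons_per_gene=(10, 10), noise_sd=0.0, covariate_effect_sd=0.0,
                    frac_eqtl_exons=0, frac_de_exons=0, frac_prs_exons=0,
                    n_core_genes=1, n_rare_genes=1, eqtl_beta=1.0,
                    prs_expr_beta=0.0, n_causal_prs_snps=5, n_cells=10)
    b = simulate_cohort(cfg)
    exon_id, snp_id, beta = b.truth.eqtl.iloc[0]
    gene = b.features.set_index("feature_id").loc[exon_id, "gene_id"]
    d = b.genotypes.dosages[snp_id].to_numpy()
    y = b.gene_expr.loc[gene].to_numpy()
    slope = np.polyfit(d, y, 1)[0]
    assert slope == pytest.approx(beta / 10, abs=1e-10)


def test_transcript_and_gene_values_are_exon_means(small_bundle):
    feats = small_bundle.features
    exons = feats[feats["level"] == "exon"]
    gene = exons["gene_id"].iloc[0]
    members = exons.loc[exons["gene_id"] == gene, "feature_id"]
    np.testing.assert_allclose(
        small_bundle.gene_expr.loc[gene],
        small_bundle.exon_expr.loc[members].mean(axis=0), atol=1e-12)
    tx = exons["transcript_id"].iloc[0]
    tmembers = exons.loc[exons["transcript_id"] == tx, "feature_id"]
    np.testing.assert_allclose(
        small_bundle.transcript_expr.loc[tx],
        small_bundle.exon_expr.loc[tmembers].mean(axis=0), atol=1e-12)


def test_refitting_generator_recovers_planted_de_beta():
    """The generating model's diagnosis effect is covered by its 95% CI."""
    from exqtl.association import fit_feature_association

    covered = 0
    for s in range(60):
        cfg = SimConfig(seed=s, n_samples=200, n_snps=10, n_genes=5,
                        exons_per_gene=(3, 3), frac_eqtl_exons=0,
                        frac_de_exons=0.1, de_beta=0.5, frac_prs_exons=0,
                        n_core_genes=0, n_rare_genes=0, n_causal_prs_snps=2,
                        n_cells=10)
        b = simulate_cohort(cfg)
        exon_id, beta = b.truth.de.iloc[0]
        row = fit_feature_association(b.exon_expr.loc[exon_id],
                                      b.diagnosis.to_numpy(), b.covariates)
        half = stats.t.ppf(0.975, row["df"]) * row["se"]
        covered += abs(row["beta"] - beta) <= half
    assert covered >= 53   # 95% CI coverage with binomial slack (>=88%)


def test_gwas_null_pvalues_uniform():
    cfg = SimConfig(seed=21, n_samples=50, n_snps=5000, n_genes=4,
                    n_causal_prs_snps=0, frac_eqtl_exons=0, frac_de_exons=0,
                    frac_prs_exons=0, n_core_genes=0, n_rare_genes=0, n_cells=10)
    b = simulate_cohort(cfg)
    p = b.gwas["SCZ"]["p"].to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_rare_list_contains_core_genes(small_bundle):
    assert set(small_bundle.truth.core_genes) <= set(small_bundle.rare_genes)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimConfig(n_samples=0).validate()
    with pytest.raises(ConfigError):
        SimConfig(maf_range=(0.2, 0.1)).validate()
    with pytest.raises(ConfigError):
        SimConfig(frac_eqtl_exons=1.5).validate()
    with pytest.raises(ConfigError):
        SimConfig(celltype_bias_target="nope").validate()


# ----------------------------------------------------------------- cells

def test_cells_single_type_and_determinism():
    c1 = simulate_cells(50, ["only"], [1.0], [f"G{i}" for i in range(5)], seed=2)
    assert set(c1.labels) == {"only"}
    c2 = simulate_cells(50, ["only"], [1.0], [f"G{i}" for i in range(5)], seed=2)
    pd.testing.assert_frame_equal(c1.expr, c2.expr)


def test_cells_unbiased_top_quantile_matches_proportions():
    """Without planted bias the top-quantile label mix is the base mix."""
    from exqtl.celltype import cell_scores, top_fraction_cells

    genes = [f"G{i:03d}" for i in range(60)]
    props = [0.5, 0.3, 0.2]
    cells = simulate_cells(4000, ["A", "B", "C"], props, genes,
                           bias_genes=genes[:10], bias_target="A",
                           bias_factor=1.0, seed=13)
    scores, _ = cell_scores(cells, genes[:10])
    top = top_fraction_cells(scores, 0.25)
    frac_a = (cells.labels.loc[top] == "A").mean()
    n = len(top)
    assert abs(frac_a - 0.5) <= 3 * np.sqrt(0.5 * 0.5 / n)


def test_cells_unknown_bias_target_rejected():
    with pytest.raises(ConfigError):
        simulate_cells(10, ["A"], [1.0], ["G1"], bias_genes=["G1"],
                       bias_target="B", bias_factor=2.0, seed=1)
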
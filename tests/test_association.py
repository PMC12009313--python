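"""Linear-model engine, BH FDR and the per-gene min-p recalibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from exqtl.association import (bh_fdr, covariate_design, fit_feature_association,
                               fit_matrix_association, multilevel_fdr, residualize)
from exqtl.errors import InputError, SingularDesignError


def test_exact_fit_recovers_slope():
    x = np.arange(10, dtype=float)
    row = fit_feature_association(3.0 * x, x)
    assert row["beta"] == pytest.approx(3.0, abs=1e-12)
    assert row["p"] == pytest.approx(0.0, abs=1e-12)


def test_engine_matches_statsmodels_on_random_instances(rng):
    """beta/se/t/p agree with an independent OLS fit to 1e-8."""
    for _ in range(30):
        n, k = 20, 3
        x = rng.standard_normal(n)
        C = pd.DataFrame(rng.standard_normal((n, k)),
                         columns=list("abc"),
                         index=[f"S{i}" for i in range(n)])
        y = rng.standard_normal(n)
        row = fit_feature_association(y, x, C)
        X = sm.add_constant(np.column_stack([x, C.to_numpy()]))
        fit = sm.OLS(y, X).fit()
        assert row["beta"] == pytest.approx(fit.params[1], abs=1e-8)
        assert row["se"] == pytest.approx(fit.bse[1], abs=1e-8)
        assert row["t"] == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-8)


def test_matrix_association_equals_per_feature(rng, random_covars):
    n = len(random_covars)
    x = rng.standard_normal(n)
    Y = pd.DataFrame(rng.standard_normal((50, n)),
                     index=[f"F{i:03d}" for i in range(50)],
                     columns=random_covars.index)
    table = fit_matrix_association(Y, x, random_covars)
    for i in [0, 7, 49]:
        row = fit_feature_association(Y.iloc[i], x, random_covars,
                                      feature_id=Y.index[i])
        for col in ("beta", "se", "t", "p"):
            assert table.iloc[i][col] == pytest.approx(row[col], abs=1e-10)


def test_matrix_association_permutation_invariance(rng, random_covars):
    n = len(random_covars)
    x = rng.standard_normal(n)
    Y = pd.DataFrame(rng.standard_normal((10, n)), columns=random_covars.index)
    base = fit_matrix_association(Y, x, random_covars)
    perm = rng.permutation(n)
    shuffled = fit_matrix_association(Y.iloc[:, perm], x[perm],
                                      random_covars.iloc[perm])
    np.testing.assert_allclose(base["beta"], shuffled["beta"], atol=1e-10)
    np.testing.assert_allclose(base["p"], shuffled["p"], atol=1e-10)


def test_degenerate_feature_flagged(rng, random_covars):
    n = len(random_covars)
    Y = pd.DataFrame([np.full(n, 5.0)], index=["flat"], columns=random_covars.index)
    table = fit_matrix_association(Y, rng.standard_normal(n), random_covars)
    row = table.iloc[0]
    assert row["beta"] == 0.0 and row["p"] == 1.0 and bool(row["degenerate"])
    assert np.isnan(row["se"])


def test_singular_design_names_collinear_column(rng):
    n = 30
    x = rng.standard_normal(n)
    C = pd.DataFrame({"dup": x}, index=[f"S{i}" for i in range(n)])
    with pytest.raises(SingularDesignError) as err:
        fit_feature_association(rng.standard_normal(n), x, C)
    assert "dup" in str(err.value) or "x" in str(err.value)


def test_type_one_error_rate_calibrated(rng):
    """Null features against a random predictor reject at ~5%."""
    n, m = 300, 4000
    x = rng.standard_normal(n)
    Y = pd.DataFrame(rng.standard_normal((m, n)))
    table = fit_matrix_association(Y, x)
    frac = float((table["p"] < 0.05).mean())
    assert 0.04 <= frac <= 0.06


# ------------------------------------------------------------ residualize

def test_residualize_intercept_only_centers(rng):
    Y = pd.DataFrame(rng.standard_normal((5, 12)))
    R = residualize(Y)
    np.testing.assert_allclose(R.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(R, Y.sub(Y.mean(axis=1), axis=0), atol=1e-12)


def test_residualize_matches_hat_matrix_and_orthogonality(rng, random_covars):
    n = len(random_covars)
    Y = pd.DataFrame(rng.standard_normal((8, n)), columns=random_covars.index)
    R = residualize(Y, random_covars)
    X = np.column_stack([np.ones(n), covariate_design(random_covars).to_numpy()])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    np.testing.assert_allclose(R.to_numpy(), Y.to_numpy() @ (np.eye(n) - H), atol=1e-8)
    assert np.abs(R.to_numpy() @ X).max() < 1e-8


# ------------------------------------------------------------------ BH FDR

def test_bh_single_p_is_identity():
    assert bh_fdr([0.03]) == pytest.approx([0.03])


def test_bh_hand_computed_step_up():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=200)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(InputError):
        bh_fdr([0.5, 1.2])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_monotone_in_sorted_p(p):
    q = bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


# ---------------------------------------------------------- multilevel FDR

def _tab(pairs):
    return pd.DataFrame([{"feature_id": f, "beta": 1.0, "p": p} for f, p in pairs])


def test_multilevel_hand_example():
    table = _tab([("A1", 0.5), ("A2", 0.01), ("A3", 0.2), ("B1", 0.04)])
    mapping = {"A1": "A", "A2": "A", "A3": "A", "B1": "B"}
    out = multilevel_fdr(table, mapping)
    assert list(out["gene_id"]) == ["A", "B"]
    assert list(out["selected_feature_id"]) == ["A2", "B1"]
    np.testing.assert_allclose(out["p"], [0.01, 0.04])
    np.testing.assert_allclose(out["fdr"], [0.02, 0.04])


def test_multilevel_tie_breaks_lexicographically():
    table = _tab([("E002", 0.01), ("E001", 0.01)])
    out = multilevel_fdr(table, {"E001": "G", "E002": "G"})
    assert out.loc[0, "selected_feature_id"] == "E001"


def test_multilevel_reduces_to_bh_with_one_feature_per_gene(rng):
    p = rng.uniform(size=40)
    table = _tab([(f"F{i}", p[i]) for i in range(40)])
    out = multilevel_fdr(table, {f"F{i}": f"G{i}" for i in range(40)})
    merged = out.set_index("selected_feature_id").loc[[f"F{i}" for i in range(40)]]
    np.testing.assert_allclose(merged["fdr"], bh_fdr(p), atol=1e-12)


def test_multilevel_invariant_to_row_order(rng):
    table = _tab([(f"F{i}", p) for i, p in enumerate(rng.uniform(size=30))])
    mapping = {f"F{i}": f"G{i % 10}" for i in range(30)}
    out1 = multilevel_fdr(table, mapping)
    out2 = multilevel_fdr(table.sample(frac=1, random_state=7), mapping)
    pd.testing.assert_frame_equal(out1, out2)


def test_multilevel_unmapped_feature_errors():
    with pytest.raises(InputError, match="F1"):
        multilevel_fdr(_tab([("F0", 0.1), ("F1", 0.2)]), {"F0": "G"})


# ------------------------------------------------------- covariate design

def test_covariate_design_derives_rin2_and_dummy_codes():
    cov = pd.DataFrame({
        "RIN": [6.0, 8.0],
        "CoD": ["natural", "violent"],
    }, index=["a", "b"])
    design = covariate_design(cov)
    np.testing.assert_allclose(design["RIN2"], [36.0, 64.0])
    assert "CoD[violent]" in design.columns       # "natural" is the reference
    assert "CoD[natural]" not in design.columns
    np.testing.assert_allclose(design["CoD[violent]"], [0.0, 1.0])


def test_covariate_design_rejects_missing_values():
    cov = pd.DataFrame({"age": [40.0, np.nan]}, index=["a", "b"])
    with pytest.raises(InputError, match="b"):
        covariate_design(cov)
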
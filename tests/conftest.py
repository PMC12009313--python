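import numpy as np
import pandas as pd
import pytest

from exqtl.simulate import SimConfig, simulate_cohort


SMALL = SimConfig(
    seed=3, n_samples=80, n_snps=60, n_genes=20, exons_per_gene=(3, 6),
    n_causal_prs_snps=10, n_core_genes=3, n_rare_genes=6,
    frac_eqtl_exons=0.05, frac_de_exons=0.05, frac_prs_exons=0.05,
    n_cells=300,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One compact cohort shared by read-only tests."""
    return simulate_cohort(SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_covars(rng):
    n = 40
    idx = [f"S{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame({
        "age": rng.uniform(20, 80, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "RIN": rng.uniform(6, 9, n),
    }, index=idx)
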
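import numpy as np
import pandas as pd
import pytest

import lipidwgs as lw


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-ancestry cohort with one planted dominant gene."""
    cfg = lw.CohortConfig(
        n_samples={"EA": 600, "AA": 400},
        n_variants=80,
        monogenic=[lw.MonogenicGene("LDLR", "dominant", 30.0, 0.02)],
        seed=11,
    )
    gm = lw.simulate_genotypes(cfg)
    pheno = lw.simulate_phenotypes(gm, cfg)
    return cfg, gm, pheno


@pytest.fixture(scope="session")
def small_landscape():
    cfg = lw.LandscapeConfig(n_cell_types=30, n_genes=8, n_bins=300, seed=11)
    return cfg, lw.simulate_regulatory_landscape(cfg)


@pytest.fixture()
def covariates():
    def _make(pheno: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({
            "age": pheno["age"],
            "age2": pheno["age"] ** 2,
            "sex": pheno["sex"],
        })
    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
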
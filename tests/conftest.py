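import numpy as np
import pandas as pd
import pytest

from survgwas.simulate import SimConfig, simulate_dataset, with_encoded


def encoded_cohort(cohort: pd.DataFrame, pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort joined with its encoded 0/1 design columns (and PCs if given)."""
    return with_encoded(cohort, pcs)


@pytest.fixture(scope="session")
def small_null_study():
    """300 subjects x 300 null SNPs: no genetic or clinical effects."""
    cfg = SimConfig(n_subjects=300, n_variants=300, seed=11, ld_rho=0.4,
                    deafness_gene_fraction=0.25, n_genes=20)
    g, cohort, genes, deafness = simulate_dataset(cfg)
    return g, encoded_cohort(cohort), genes, deafness


@pytest.fixture(scope="session")
def planted_study():
    """800 subjects with clinical effects and two planted causal SNPs."""
    cfg = SimConfig(
        n_subjects=800, n_variants=200, seed=23, ld_rho=0.3,
        n_genes=20, deafness_gene_fraction=0.25, member_variant_fraction=0.3,
        causal_effects={"snp000050": np.log(2.0), "snp000120": np.log(1.8)},
        clinical_effects={"age_ge50": np.log(1.7), "t34": np.log(1.7),
                          "conc_cis_high": np.log(1.5)},
    )
    g, cohort, genes, deafness = simulate_dataset(cfg)
    return cfg, g, encoded_cohort(cohort), genes, deafness
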
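import numpy as np
import pytest

from liverewas.phenotypes import derive_phenotypes
from liverewas.pipeline import _ewas_covariate_table
from liverewas.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = GeneratorConfig(
        n_samples_per_cohort=300, n_cpgs=150, n_true_cpgs=5, n_snps=30,
        n_genes=8, seed=11,
    )
    return generate_cohort(cfg, cohort_mean_age=50.0, seed=11, name="fix")


@pytest.fixture(scope="session")
def small_cohort_derived(small_cohort):
    tab = small_cohort.covariates.join(small_cohort.phenotypes)
    return derive_phenotypes(tab, tg_unit="mmol/l")


@pytest.fixture(scope="session")
def small_cohort_covariates(small_cohort_derived):
    return _ewas_covariate_table(small_cohort_derived, n_pcs=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
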
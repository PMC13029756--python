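import numpy as np
import pytest

from agevar import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20k individuals, 20 SNPs, age-varying effects for downstream stages."""
    cfg = CohortConfig(
        n_individuals=20_000,
        n_snps=20,
        maf=0.4,
        beta_age=0.05,
        beta_g=0.3,
        theta=0.01,
        beta_u=0.5,
        noise_sd=1.0,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no SNP-by-age interaction (theta = 0)."""
    cfg = CohortConfig(
        n_individuals=20_000,
        n_snps=20,
        maf=0.4,
        beta_age=0.05,
        beta_g=0.3,
        theta=0.0,
        beta_u=0.5,
        seed=43,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
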
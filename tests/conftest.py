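import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    from meqtlmr.simulate import simulate_study

    return simulate_study(
        seed=7,
        n_cohort1=220,
        n_cohort2_ewas=140,
        n_meqtl=300,
        n_outcome=900,
        n_hep=56,
        n_background_probes=12,
    )


@pytest.fixture
def toy_pheno(rng):
    """Covariate table with the standard columns for 200 samples."""
    from meqtlmr.simulate import simulate_covariates

    return simulate_covariates(200, rng)
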
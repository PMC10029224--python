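import numpy as np
import pytest

from frailpheno.cohort import default_params, generate_cohort
from frailpheno.distributions import shrink_boundary
from frailpheno.model import BetaFrailtyRegressor
from frailpheno.pipeline import RunConfig, prepare_table
from frailpheno.validation import loo_for_model

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=998) at a fixed seed."""
    return generate_cohort(default_params(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def scored_cohort():
    """Default cohort, imputed and scored (FI, count-PFP columns)."""
    return prepare_table(RunConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def study_fits(scored_cohort):
    """The three study models fitted on the default cohort at a reduced budget.

    Shared across agreement/ordering tests so the expensive MCMC runs once.
    """
    y = shrink_boundary(scored_cohort["fi"].to_numpy(dtype=float), len(scored_cohort))
    fits = {}
    for kind in ("referent", "gait_speed", "full_pfp"):
        m = BetaFrailtyRegressor(spec=kind, chains=2, iterations=700, seed=COHORT_SEED)
        m.fit(scored_cohort, y)
        fits[kind] = m
    return fits


@pytest.fixture(scope="session")
def study_loos(study_fits):
    return {k: loo_for_model(m) for k, m in study_fits.items()}
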
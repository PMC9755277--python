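import numpy as np
import pytest

from mddineq.cohort import FOOD_COLUMNS, apply_filter_cascade, compute_mdd, recode_covariates
from mddineq.synthetic import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized default-condition cohort shared across tests."""
    cfg = GeneratorConfig(n_children=6000, seed=11)
    table = recode_covariates(generate_survey(cfg))
    cohort, report = apply_filter_cascade(table)
    return cohort, report


@pytest.fixture(scope="session")
def cohort_outcome(default_cohort):
    cohort, _ = default_cohort
    return compute_mdd(cohort[FOOD_COLUMNS])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
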
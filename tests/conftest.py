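import logging

import pytest

from rsrates import (
    CohortConfig, SimConfig, build_mortality_cohort, fit_hierarchical_logit,
    generate_population,
)

logging.getLogger("rsrates").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_claims():
    """Desk-scale mortality-measure dataset: 30 hospitals x 60 cases."""
    cfg = SimConfig(
        seed=11, n_hospitals=30,
        hospital_volume_distribution={"kind": "fixed", "n": 60},
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_claims):
    return build_mortality_cohort(small_claims, CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    fit, est = fit_hierarchical_logit(
        small_cohort.table, small_cohort.covariate_columns
    )
    return fit, est
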
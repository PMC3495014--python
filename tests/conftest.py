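"""Shared fixtures: one default synthetic trial and its two nested fits.

The heavy objects are session-scoped so that recovery, discrimination,
shrinkage and VPC checks all reuse the same cohort and fits.
"""

import pytest
from hypothesis import HealthCheck, settings

from tgikit import (
    ModelVariant,
    TrialDesign,
    fit,
    generate_cohort,
    reference_estimates,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    return reference_estimates()


@pytest.fixture(scope="session")
def default_cohort(truth):
    return generate_cohort(TrialDesign(), truth, seed=1)


@pytest.fixture(scope="session")
def analysis_patients(default_cohort):
    return default_cohort.analysis_patients()


@pytest.fixture(scope="session")
def model2_fit(analysis_patients):
    result = fit(analysis_patients, variant=ModelVariant.MODEL2, compute_se=True)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def model1_fit(analysis_patients):
    result = fit(analysis_patients, variant=ModelVariant.MODEL1, compute_se=False)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def small_cohort(truth):
    return generate_cohort(TrialDesign(n_total=60, n_active=40), truth, seed=5)
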
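import numpy as np
import pytest

from lvfda import FitOptions, SyntheticConfig, generate_cohort

# reduced option set used by the small-cohort tests: rare binary covariates
# (diabetes at 10%) can be constant in tiny samples, which the fitter
# correctly rejects, so small fixtures restrict the scalar design
SMALL_SCALARS = ("age", "ultrafiltrate", "ivc_diameter", "sex")


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-patient cohort for fast fitting tests."""
    return generate_cohort(SyntheticConfig(n_patients=24, seed=0), seed=101)


@pytest.fixture(scope="session")
def small_options():
    return FitOptions(scalar_terms=SMALL_SCALARS)


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study size (70 patients, 3 x 7 SBP)."""
    return generate_cohort(SyntheticConfig(seed=0), seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
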
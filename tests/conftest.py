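import numpy as np
import pytest

import voripk as vp


@pytest.fixture(scope="session")
def final_spec():
    return vp.final_model_spec()


@pytest.fixture(scope="session")
def truth():
    return vp.final_model_params()


@pytest.fixture(scope="session")
def base_spec():
    return vp.base_model_spec()


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects simulated under the final model."""
    return vp.generate_cohort(vp.CohortConfig(n_subjects=40), seed=7)


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study scale (167 subjects, ~232 troughs)."""
    return vp.generate_cohort(vp.CohortConfig(n_subjects=167), seed=11)


@pytest.fixture(scope="session")
def study_design(study_cohort):
    return vp.CohortDesign.from_subjects(vp.apply_m1(study_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
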
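import numpy as np
import pytest

import sbpcourse as sc


@pytest.fixture(scope="session")
def linear_config():
    """Small linear cohort config used across modules."""
    return sc.SyntheticConfig(
        n_patients=80,
        true_alpha=np.array([130.0, -0.28]),
        true_G=np.diag([100.0, 0.25]),
        true_sigma2=64.0,
        outcome_coefficients=sc.default_outcome_coefficients(1),
        optional_measurement_prob=0.3,
        dropout_prob=0.05,
        seed=12345,
    )


@pytest.fixture(scope="session")
def linear_cohort(linear_config):
    return sc.generate_cohort(linear_config)


@pytest.fixture(scope="session")
def linear_course(linear_cohort):
    """Course fitted on the full small cohort (outcome check bypassed)."""
    return sc.fit_reference_course(
        linear_cohort,
        sc.CourseSpec(1, "functional_independence"),
        sc.FitConfig(check_outcome=False, seed=0),
    )


@pytest.fixture(scope="session")
def truth_course(linear_config):
    """A course carrying the generating parameters (no fitting noise)."""
    return sc.ReferenceCourse(
        spec=sc.CourseSpec(1, "functional_independence"),
        alpha=linear_config.true_alpha,
        G=linear_config.true_G,
        sigma2=linear_config.true_sigma2,
    )


def make_patient(times, sbp, pid="p0", **kwargs):
    defaults = dict(
        age=70.0, sex=1, nihss_baseline=12.0, hypertension=0, mtici_success=1,
        outcomes={"functional_independence": 1},
    )
    defaults.update(kwargs)
    return sc.PatientRecord(patient_id=pid, times=times, sbp=sbp, **defaults)


@pytest.fixture
def patient_factory():
    return make_patient
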
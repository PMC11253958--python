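import numpy as np
import pytest

from iogfr.pk_clearance import (
    ClearanceStudy,
    PatientCovariates,
    SampleObservation,
    SCHEDULES,
)

REF_TIMES = SCHEDULES["ref_10h"].times_min
OC8_TIMES = SCHEDULES["oc_8h"].times_min


@pytest.fixture
def covariates():
    return PatientCovariates(
        age_years=60.0, sex="male", race_black=False,
        weight_kg=70.0, height_cm=170.0, serum_creatinine_mg_dL=2.2,
    )


def make_study(times, concs, covariates, dose_mg=3235.0, patient_id="P1",
               study_index=1):
    samples = tuple(
        SampleObservation(float(t), float(c)) for t, c in zip(times, concs)
    )
    return ClearanceStudy(
        patient_id=patient_id, study_index=study_index, dose_mg=dose_mg,
        samples=samples, covariates=covariates,
    )


def biexp(times, A=150.0, alpha=0.05, B=50.0, beta=0.005):
    t = np.asarray(times, dtype=float)
    return A * np.exp(-alpha * t) + B * np.exp(-beta * t)


def monoexp(times, C0=200.0, k=0.005):
    t = np.asarray(times, dtype=float)
    return C0 * np.exp(-k * t)


@pytest.fixture
def biexp_study(covariates):
    return make_study(REF_TIMES, biexp(REF_TIMES), covariates)


@pytest.fixture
def monoexp_study(covariates):
    return make_study(OC8_TIMES, monoexp(OC8_TIMES), covariates)
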
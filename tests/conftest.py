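import pytest

from hemovisc import (
    GeneratorConfig,
    CohortSpec,
    ModelConstants,
    SubjectRecord,
    generate,
    reference_models,
)

# Reference cohort means used as a worked example throughout.
MEAN_HEIGHT = 168.80
MEAN_WEIGHT = 74.11
MEAN_HR = 72.10
MEAN_SBP = 128.59
MEAN_DBP = 74.16
MEAN_EDD = 50.27
MEAN_ESD = 34.12
MEAN_SV = 92.21
MEAN_CO = 6636.71
MEAN_PP = 54.43
MEAN_BSA = 1.82


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture
def mean_subject():
    """A subject whose raw measurements equal the reference cohort means."""
    return SubjectRecord(
        subject_id="mean",
        height_cm=MEAN_HEIGHT,
        weight_kg=MEAN_WEIGHT,
        heart_rate_bpm=MEAN_HR,
        sbp_mmHg=MEAN_SBP,
        dbp_mmHg=MEAN_DBP,
        lv_edd_mm=MEAN_EDD,
        lv_esd_mm=MEAN_ESD,
        measured_viscosity_cp=19.24,
    )


@pytest.fixture(scope="session")
def ref_models():
    return reference_models()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """79 subjects with viscosity planted exactly from the reference models."""
    return generate(CohortSpec(n=79), GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_records(noiseless_cohort):
    return noiseless_cohort[0]
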
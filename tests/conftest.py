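import numpy as np
import pytest

from ovarisk import CoefficientSet, ParticipantRecord, ReferenceStandard, UltrasoundExam


@pytest.fixture
def exam_benign():
    """Smooth unilocular cyst: B-features only, no U-score characteristics."""
    return UltrasoundExam(
        lesion_present=True,
        max_lesion_diameter=50.0,
        max_solid_diameter=0.0,
        multilocular=False,
        solid_areas=False,
        bilateral=False,
        ascites=False,
        metastases=False,
        more_than_10_locules=False,
        papillation_count=0,
        acoustic_shadows=False,
        benign_features=frozenset({"B2"}),
        malignant_features=frozenset(),
    )


@pytest.fixture
def exam_malignant():
    """Large solid lesion with ascites and papillations: M-features only."""
    return UltrasoundExam(
        lesion_present=True,
        max_lesion_diameter=110.0,
        max_solid_diameter=70.0,
        multilocular=True,
        solid_areas=True,
        bilateral=False,
        ascites=True,
        metastases=False,
        more_than_10_locules=False,
        papillation_count=4,
        acoustic_shadows=False,
        benign_features=frozenset(),
        malignant_features=frozenset({"M1", "M3"}),
    )


@pytest.fixture
def roma_unit_coefficients():
    """Synthetic ROMA coefficients with easily-checked algebra."""
    return CoefficientSet(
        model_id="roma",
        version_label="unit-test",
        strata={
            "premenopausal": {"intercept": 0.0, "ln_he4": 0.0, "ln_ca125": 0.0},
            "postmenopausal": {"intercept": 1.0, "ln_he4": 0.0, "ln_ca125": 0.0},
        },
    )


@pytest.fixture
def srrisk_unit_coefficients():
    coeffs = {"intercept": -1.0, "oncology_centre": 0.5}
    coeffs.update({f"B{i}": -0.5 for i in range(1, 6)})
    coeffs.update({f"M{i}": 1.0 for i in range(1, 6)})
    return CoefficientSet(model_id="srrisk", version_label="unit-test", strata={"all": coeffs})


@pytest.fixture
def adnex_zero_coefficients():
    """All linear predictors identically zero -> uniform class probabilities."""
    zero = {"intercept": 0.0}
    return CoefficientSet(
        model_id="adnex",
        version_label="unit-test-zero",
        strata={
            "with_ca125": {
                cls: dict(zero) for cls in ("borderline", "stage1", "stage2_4", "secondary_metastatic")
            }
        },
    )


def make_record(pid="p1", histology="benign", source="surgery", followup="unknown", **kw):
    defaults = dict(
        participant_id=pid,
        age=44.0,
        menstruated_last_12m="yes",
        menopausal_status="premenopausal",
        ca125=30.0,
        he4=50.0,
        cohort_tag="pre_change",
    )
    defaults.update(kw)
    return ParticipantRecord(
        reference=ReferenceStandard(
            source=source, histology_category=histology, followup_cancer_diagnosis=followup
        ),
        **defaults,
    )
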
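"""Index-test scorers: U-score, RMI, ROMA, simple rules (+risk), ADNEX, ORADS."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovarisk import (
    CoefficientSet,
    UltrasoundExam,
    compute_adnex,
    compute_rmi,
    compute_roma,
    compute_simple_rules,
    compute_simple_rules_risk,
    compute_u_score,
    dichotomize_score,
    load_coefficients,
    map_orads,
)
from ovarisk.models import ConfigurationError, RiskScore


def _exam(**kw):
    base = dict(
        lesion_present=True,
        max_lesion_diameter=60.0,
        max_solid_diameter=10.0,
        multilocular=False,
        solid_areas=False,
        bilateral=False,
        ascites=False,
        metastases=False,
        more_than_10_locules=False,
        papillation_count=0,
        acoustic_shadows=False,
        benign_features=frozenset(),
        malignant_features=frozenset(),
    )
    base.update(kw)
    return UltrasoundExam(**base)


# ------------------------------------------------------------------ U / RMI


@pytest.mark.parametrize(
    "features,expected",
    [
        ({}, 0),
        ({"ascites": True}, 1),
        ({"multilocular": True, "solid_areas": True, "ascites": True}, 3),
        ({"multilocular": True, "bilateral": True}, 3),
    ],
)
def test_u_score(features, expected):
    assert compute_u_score(_exam(**{k: v for k, v in features.items()})) == expected


def test_u_score_unknown_flag_gives_missing():
    assert compute_u_score(_exam(ascites=None)) is None
    assert compute_u_score(None) is None


def test_rmi_product_and_thresholding():
    assert compute_rmi(100.0, 3, "premenopausal").numeric_value == 300.0
    assert compute_rmi(100.0, 3, "postmenopausal").numeric_value == 900.0
    assert compute_rmi(500.0, 0, "premenopausal").numeric_value == 0.0
    score = compute_rmi(84.0, 1, "premenopausal")
    assert score.numeric_value == 84.0
    assert dichotomize_score(score, 250.0).state == "negative"
    assert compute_rmi(None, 3, "premenopausal").status == "missing_inputs"


def test_rmi_monotone_in_ca125():
    values = [compute_rmi(c, 3, "premenopausal").numeric_value for c in (10, 50, 200, 900)]
    assert values == sorted(values) and values[0] < values[-1]


# --------------------------------------------------------------------- ROMA


def test_roma_logistic_midpoint(roma_unit_coefficients):
    score = compute_roma(30.0, 50.0, "premenopausal", roma_unit_coefficients)
    assert score.numeric_value == pytest.approx(50.0)


def test_roma_stratum_switch_changes_score(roma_unit_coefficients):
    pre = compute_roma(30.0, 50.0, "premenopausal", roma_unit_coefficients)
    post = compute_roma(30.0, 50.0, "postmenopausal", roma_unit_coefficients)
    assert pre.numeric_value != post.numeric_value


def test_roma_rejects_nonpositive_markers(roma_unit_coefficients):
    with pytest.raises(ValueError):
        compute_roma(0.0, 50.0, "premenopausal", roma_unit_coefficients)
    assert compute_roma(None, 50.0, "premenopausal", roma_unit_coefficients).status == "missing_inputs"


@settings(deadline=None, max_examples=50)
@given(
    he4=st.floats(min_value=1.0, max_value=2000.0),
    ca125=st.floats(min_value=1.0, max_value=5000.0),
)
def test_roma_monotone_in_he4_with_positive_coefficient(he4, ca125):
    coeffs = load_coefficients("roma")
    lo = compute_roma(ca125, he4, "premenopausal", coeffs).numeric_value
    hi = compute_roma(ca125, 2 * he4, "premenopausal", coeffs).numeric_value
    assert hi > lo
    assert 0.0 <= lo <= 100.0 and 0.0 <= hi <= 100.0


# ------------------------------------------------------------- simple rules


def test_simple_rules_examples():
    assert compute_simple_rules(_exam(malignant_features=frozenset({"M1"}))).category == "malignant"
    assert compute_simple_rules(_exam(benign_features=frozenset({"B2"}))).category == "benign"
    assert (
        compute_simple_rules(
            _exam(benign_features=frozenset({"B1"}), malignant_features=frozenset({"M3"}))
        ).category
        == "inconclusive"
    )
    assert compute_simple_rules(_exam()).category == "inconclusive"
    assert compute_simple_rules(_exam(benign_features=None)).status == "missing_inputs"


def test_simple_rules_exhaustive_truth_table():
    """All 2^10 feature combinations against an independent oracle."""
    b_codes = ("B1", "B2", "B3", "B4", "B5")
    m_codes = ("M1", "M2", "M3", "M4", "M5")
    n_checked = 0
    for b_bits in itertools.product((0, 1), repeat=5):
        for m_bits in itertools.product((0, 1), repeat=5):
            b = frozenset(c for c, bit in zip(b_codes, b_bits) if bit)
            m = frozenset(c for c, bit in zip(m_codes, m_bits) if bit)
            nb, nm = sum(b_bits), sum(m_bits)
            if nm >= 1 and nb == 0:
                expected = "malignant"
            elif nb >= 1 and nm == 0:
                expected = "benign"
            else:
                expected = "inconclusive"
            got = compute_simple_rules(_exam(benign_features=b, malignant_features=m))
            assert got.category == expected
            n_checked += 1
    assert n_checked == 1024


# -------------------------------------------------------- simple rules risk


def test_srrisk_intercept_only(srrisk_unit_coefficients):
    score = compute_simple_rules_risk(_exam(), "non_oncology", srrisk_unit_coefficients)
    assert score.numeric_value == pytest.approx(100.0 / (1 + math.e), rel=1e-9)


def test_srrisk_monotone_in_malignant_feature(srrisk_unit_coefficients):
    base = compute_simple_rules_risk(_exam(), "non_oncology", srrisk_unit_coefficients)
    plus = compute_simple_rules_risk(
        _exam(malignant_features=frozenset({"M2"})), "non_oncology", srrisk_unit_coefficients
    )
    onc = compute_simple_rules_risk(_exam(), "oncology", srrisk_unit_coefficients)
    assert plus.numeric_value > base.numeric_value
    assert onc.numeric_value > base.numeric_value
    for s in (base, plus, onc):
        assert 0.0 <= s.numeric_value <= 100.0


# -------------------------------------------------------------------- ADNEX


def test_adnex_uniform_probabilities_with_zero_coefficients(adnex_zero_coefficients):
    score = compute_adnex(44.0, 30.0, _exam(), "non_oncology", adnex_zero_coefficients)
    probs = score.extra["class_probabilities"]
    assert all(p == pytest.approx(0.2) for p in probs.values())
    assert score.numeric_value == pytest.approx(80.0)


def test_adnex_probabilities_sum_to_one():
    coeffs = load_coefficients("adnex")
    score = compute_adnex(44.0, 120.0, _exam(solid_areas=True, max_solid_diameter=30.0), "oncology", coeffs)
    probs = score.extra["class_probabilities"]
    assert sum(probs.values()) == pytest.approx(1.0)
    assert 0.0 <= score.numeric_value <= 100.0


def test_adnex_monotone_in_ca125_with_positive_coefficients():
    coeffs = load_coefficients("adnex")  # all malignant-class ln_ca125 coefficients > 0
    risks = [
        compute_adnex(44.0, c, _exam(), "non_oncology", coeffs).numeric_value
        for c in (5.0, 20.0, 80.0, 320.0, 1280.0)
    ]
    assert risks == sorted(risks) and risks[0] < risks[-1]


def test_adnex_missing_ca125_policies():
    coeffs = load_coefficients("adnex")
    assert compute_adnex(44.0, None, _exam(), "non_oncology", coeffs).status == "missing_inputs"
    score = compute_adnex(
        44.0, None, _exam(), "non_oncology", coeffs, ca125_missing_policy="without_ca125"
    )
    assert score.status == "computed"
    assert compute_adnex(None, 30.0, _exam(), "non_oncology", coeffs).status == "missing_inputs"


# -------------------------------------------------------------------- ORADS


def test_orads_mapping_rows():
    no_lesion = _exam(lesion_present=False, max_lesion_diameter=None, max_solid_diameter=None)
    assert map_orads(no_lesion).category == "1"
    assert dichotomize_score(map_orads(no_lesion)).state == "negative"

    simple_cyst = _exam(max_lesion_diameter=40.0, max_solid_diameter=0.0)
    assert int(map_orads(simple_cyst).category) <= 3
    assert dichotomize_score(map_orads(simple_cyst)).state == "negative"

    high_risk = _exam(solid_areas=True, ascites=True, papillation_count=4, max_solid_diameter=40.0)
    assert map_orads(high_risk).category == "5"
    assert dichotomize_score(map_orads(high_risk)).state == "positive"

    assert map_orads(None).status == "missing_inputs"


# ----------------------------------------------------------- dichotomisation


def test_dichotomize_strict_inequality_at_threshold():
    ca125_at_87 = RiskScore("ca125", numeric_value=87.0)
    assert dichotomize_score(ca125_at_87, 87.0).state == "negative"
    assert dichotomize_score(RiskScore("ca125", numeric_value=87.1), 87.0).state == "positive"
    assert dichotomize_score(RiskScore("rmi1", numeric_value=300.0), 250.0).state == "positive"


def test_dichotomize_passthrough_states():
    assert dichotomize_score(RiskScore("simple_rules", category="inconclusive")).state == "inconclusive"
    assert dichotomize_score(RiskScore("rmi1", status="missing_inputs"), 250.0).state == "missing"
    with pytest.raises(ConfigurationError):
        dichotomize_score(RiskScore("rmi1", numeric_value=100.0))  # numeric needs threshold


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=50), st.data())
def test_threshold_nesting_property(values, data):
    """positives at the higher threshold are a subset of those at the lower."""
    t1 = data.draw(st.floats(min_value=0, max_value=99))
    t2 = data.draw(st.floats(min_value=t1, max_value=100))
    pos1 = {i for i, v in enumerate(values) if dichotomize_score(RiskScore("roma", numeric_value=v), t1).state == "positive"}
    pos2 = {i for i, v in enumerate(values) if dichotomize_score(RiskScore("roma", numeric_value=v), t2).state == "positive"}
    assert pos2 <= pos1
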
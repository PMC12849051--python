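"""The six index-test scorers and the ORADS lexicon mapping.

Implements:

* RMI 1 — Risk of Malignancy Index: ``U x M x CA125`` with U-score 0/1/3
  from five ultrasound characteristics and menopausal multiplier M (1
  premenopausal, 3 postmenopausal); dichotomised at 200 and 250.
* ROMA — menopause-stratified logistic predictive index on ln(HE4) and
  ln(CA 125), reported as a percentage risk; thresholds 7.4/11.4/12.5/13.1%.
* IOTA simple rules — ternary classifier from five benign (B1-B5) and five
  malignant (M1-M5) ultrasound features.
* IOTA simple rules risk — logistic model on the ten B/M features plus
  centre type; thresholds 3% and 10%.
* IOTA ADNEX — multinomial logistic model over {benign, borderline, stage 1,
  stage 2-4, secondary metastatic}; total malignancy risk = 100*(1-P(benign))
  is what gets dichotomised at 3% and 10%.
* CA 125 alone at 87 IU/mL.
* ORADS — rule-table mapping of the ultrasound lexicon to categories 1-5,
  test-positive for 4-5.

Model coefficients for ROMA, ADNEX and simple rules risk are not hard-coded:
they live in versioned JSON files under ``ovarisk/data/coefficients`` and are
loaded into :class:`CoefficientSet` objects, so alternative published
parameterisations can be swapped in.  Scorers never impute: any missing
required predictor yields a ``missing_inputs`` result.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .cohort import BENIGN_FEATURES, MALIGNANT_FEATURES, UltrasoundExam

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientSet",
    "RiskScore",
    "BinaryTestResult",
    "ConfigurationError",
    "load_coefficients",
    "default_registry",
    "compute_u_score",
    "compute_rmi",
    "compute_roma",
    "compute_simple_rules",
    "compute_simple_rules_risk",
    "compute_adnex",
    "map_orads",
    "load_orads_table",
    "dichotomize_score",
    "DEFAULT_THRESHOLDS",
]

ADNEX_CLASSES = ("benign", "borderline", "stage1", "stage2_4", "secondary_metastatic")

DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "rmi1": (200.0, 250.0),
    "roma": (7.4, 11.4, 12.5, 13.1),
    "adnex": (3.0, 10.0),
    "srrisk": (3.0, 10.0),
    "ca125": (87.0,),
}


class ConfigurationError(ValueError):
    """A model asked for a coefficient or threshold that is not registered."""


@dataclass(frozen=True)
class CoefficientSet:
    """Versioned parameters of a published risk model.

    ``strata`` maps a stratum label (e.g. ``premenopausal``; single-stratum
    models use ``all``) to a coefficient dict that must contain
    ``intercept`` (ADNEX: one dict per non-benign class).  ``transforms``
    tags per-predictor transforms; the only tags used are ``ln`` (natural
    log) and ``identity``.
    """

    model_id: str
    version_label: str
    strata: Mapping[str, Mapping]
    transforms: Mapping[str, str] = field(default_factory=dict)
    source_citation: str = ""

    def __post_init__(self) -> None:
        if not self.version_label:
            raise ValueError("version_label must be nonempty")

    def for_stratum(self, stratum: str) -> Mapping:
        try:
            return self.strata[stratum]
        except KeyError:
            raise ConfigurationError(
                f"{self.model_id} has no coefficients for stratum {stratum!r}"
            ) from None


@dataclass(frozen=True)
class RiskScore:
    model_id: str
    numeric_value: Optional[float] = None  # RMI: unitless; ROMA/ADNEX/sRRisk: %; CA125: IU/mL
    category: Optional[str] = None  # simple rules and ORADS only
    status: str = "computed"  # computed / missing_inputs
    extra: Mapping = field(default_factory=dict)  # e.g. ADNEX class probabilities


@dataclass(frozen=True)
class BinaryTestResult:
    test_id: str
    state: str  # positive / negative / inconclusive / missing


def load_coefficients(model_id: str, path=None) -> CoefficientSet:
    """Load a coefficient JSON (shipped default, or an explicit path)."""
    if path is None:
        ref = resources.files("ovarisk.data.coefficients").joinpath(f"{model_id}.json")
        payload = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            payload = json.load(fh)
    return CoefficientSet(
        model_id=payload["model_id"],
        version_label=payload["version_label"],
        strata=payload["strata"],
        transforms=payload.get("transforms", {}),
        source_citation=payload.get("source_citation", ""),
    )


def default_registry() -> dict[str, CoefficientSet]:
    """The shipped coefficient sets for the three parametric models."""
    return {m: load_coefficients(m) for m in ("roma", "adnex", "srrisk")}


# --------------------------------------------------------------------------
# RMI 1
# --------------------------------------------------------------------------

_U_FLAGS = ("multilocular", "solid_areas", "metastases", "ascites", "bilateral")


def compute_u_score(exam: Optional[UltrasoundExam]) -> Optional[int]:
    """Ultrasound U-score: one point each for multilocular cysts, solid areas,
    metastases, ascites and bilateral lesions; U=0 for 0 points, U=1 for 1,
    U=3 for 2-5.  Returns None when any of the five flags is unassessed."""
    if exam is None or not exam.scan_available:
        return None
    flags = [getattr(exam, f) for f in _U_FLAGS]
    if any(f is None for f in flags):
        return None
    count = sum(bool(f) for f in flags)
    return 0 if count == 0 else (1 if count == 1 else 3)


def compute_rmi(
    ca125: Optional[float], u: Optional[int], menopausal_status: Optional[str]
) -> RiskScore:
    """RMI 1 = U x M x CA125, M = 1 premenopausal / 3 postmenopausal."""
    if ca125 is None or u is None or menopausal_status not in (
        "premenopausal",
        "postmenopausal",
    ):
        return RiskScore("rmi1", status="missing_inputs")
    m = 1.0 if menopausal_status == "premenopausal" else 3.0
    return RiskScore("rmi1", numeric_value=u * m * ca125)


# --------------------------------------------------------------------------
# ROMA
# --------------------------------------------------------------------------


def compute_roma(
    ca125: Optional[float],
    he4: Optional[float],
    menopausal_status: str,
    coefficients: CoefficientSet,
) -> RiskScore:
    """ROMA percentage risk from the menopause-stratified predictive index
    PI = intercept + a*ln(HE4) + b*ln(CA125); ROMA% = 100*expit(PI)."""
    if ca125 is None or he4 is None:
        return RiskScore("roma", status="missing_inputs")
    if ca125 <= 0 or he4 <= 0:
        raise ValueError("ROMA requires strictly positive marker values (log transform)")
    coef = coefficients.for_stratum(menopausal_status)
    try:
        pi = coef["intercept"] + coef["ln_he4"] * np.log(he4) + coef["ln_ca125"] * np.log(ca125)
    except KeyError as exc:
        raise ConfigurationError(f"ROMA coefficient missing: {exc}") from None
    return RiskScore("roma", numeric_value=100.0 * _expit(pi))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


# --------------------------------------------------------------------------
# IOTA simple rules
# --------------------------------------------------------------------------


def compute_simple_rules(exam: Optional[UltrasoundExam]) -> RiskScore:
    """Ternary classifier: only M-features -> malignant; only B-features ->
    benign; both or neither -> inconclusive."""
    if exam is None or exam.benign_features is None or exam.malignant_features is None:
        return RiskScore("simple_rules", status="missing_inputs")
    has_b = len(exam.benign_features) > 0
    has_m = len(exam.malignant_features) > 0
    if has_m and not has_b:
        cat = "malignant"
    elif has_b and not has_m:
        cat = "benign"
    else:
        cat = "inconclusive"
    return RiskScore("simple_rules", category=cat)


def compute_simple_rules_risk(
    exam: Optional[UltrasoundExam],
    centre_type: str,
    coefficients: CoefficientSet,
) -> RiskScore:
    """Logistic malignancy risk from the ten B/M feature indicators plus
    oncology-centre type; returned in percent."""
    if exam is None or exam.benign_features is None or exam.malignant_features is None:
        return RiskScore("srrisk", status="missing_inputs")
    coef = coefficients.for_stratum("all")
    try:
        lp = coef["intercept"] + coef["oncology_centre"] * (centre_type == "oncology")
        for f in BENIGN_FEATURES:
            lp += coef[f] * (f in exam.benign_features)
        for f in MALIGNANT_FEATURES:
            lp += coef[f] * (f in exam.malignant_features)
    except KeyError as exc:
        raise ConfigurationError(f"simple rules risk coefficient missing: {exc}") from None
    return RiskScore("srrisk", numeric_value=100.0 * _expit(lp))


# --------------------------------------------------------------------------
# IOTA ADNEX
# --------------------------------------------------------------------------

_ADNEX_REQUIRED = ("max_lesion_diameter", "more_than_10_locules", "papillation_count", "acoustic_shadows", "ascites")


def compute_adnex(
    age: Optional[float],
    ca125: Optional[float],
    exam: Optional[UltrasoundExam],
    centre_type: str,
    coefficients: CoefficientSet,
    ca125_missing_policy: str = "missing",
) -> RiskScore:
    """ADNEX multinomial risks and total malignancy risk (percent).

    Predictors: age, ln(CA 125), ln(max lesion diameter), proportion of solid
    tissue (max solid diameter / max lesion diameter, clipped to [0, 1]),
    more than 10 locules, number of papillary projections (0-4), acoustic
    shadows, ascites, oncology centre.  One linear predictor per non-benign
    class against the benign reference; softmax gives class probabilities.

    ``ca125_missing_policy``: ``missing`` (default — mirrors an analysis that
    computed ADNEX only from measured CA 125) or ``without_ca125`` (use the
    coefficient file's CA125-free stratum).
    """
    if age is None or exam is None or not exam.scan_available:
        return RiskScore("adnex", status="missing_inputs")
    if any(getattr(exam, f) is None for f in _ADNEX_REQUIRED):
        return RiskScore("adnex", status="missing_inputs")
    use_ca125 = True
    if ca125 is None:
        if ca125_missing_policy == "missing":
            return RiskScore("adnex", status="missing_inputs")
        if ca125_missing_policy == "without_ca125":
            use_ca125 = False
        else:
            raise ConfigurationError(f"unknown CA125-missing policy {ca125_missing_policy!r}")
    elif ca125 <= 0:
        raise ValueError("ADNEX requires CA125 > 0 (log transform)")

    ld = exam.max_lesion_diameter
    if ld is None or ld <= 0:
        return RiskScore("adnex", status="missing_inputs")
    sd = exam.max_solid_diameter if exam.max_solid_diameter is not None else 0.0
    prop_solid = sd / ld
    if prop_solid < 0:
        raise ValueError("proportion of solid tissue below 0")
    if prop_solid > 1:
        if prop_solid > 1 + 1e-9:
            warnings.warn(
                f"proportion solid {prop_solid:.3f} clipped to 1", stacklevel=2
            )
        prop_solid = 1.0

    stratum = "with_ca125" if use_ca125 else "without_ca125"
    strata = coefficients.for_stratum(stratum)
    x = {
        "age": float(age),
        "ln_ca125": float(np.log(ca125)) if use_ca125 else 0.0,
        "ln_max_lesion_diameter": float(np.log(ld)),
        "proportion_solid": float(prop_solid),
        "more_than_10_locules": float(bool(exam.more_than_10_locules)),
        "papillation_count": float(min(int(exam.papillation_count), 4)),
        "acoustic_shadows": float(bool(exam.acoustic_shadows)),
        "ascites": float(bool(exam.ascites)),
        "oncology_centre": float(centre_type == "oncology"),
    }
    lps = {"benign": 0.0}
    for cls in ADNEX_CLASSES[1:]:
        try:
            coef = strata[cls]
            lps[cls] = coef["intercept"] + sum(
                coef[name] * value for name, value in x.items() if name in coef
            )
        except KeyError as exc:
            raise ConfigurationError(f"ADNEX coefficient missing for {cls}: {exc}") from None
    z = np.array([lps[c] for c in ADNEX_CLASSES])
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    probs = dict(zip(ADNEX_CLASSES, (float(v) for v in p)))
    return RiskScore(
        "adnex",
        numeric_value=100.0 * (1.0 - probs["benign"]),
        extra={"class_probabilities": probs},
    )


# --------------------------------------------------------------------------
# ORADS mapping
# --------------------------------------------------------------------------


def load_orads_table(path=None) -> list[dict]:
    """Ordered rule list mapping ultrasound lexicon features to ORADS 1-5."""
    if path is None:
        ref = resources.files("ovarisk.data").joinpath("orads_mapping.json")
        payload = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            payload = json.load(fh)
    return payload["rules"]


_ORADS_FEATURE_GETTERS = {
    "lesion_present": lambda e: e.lesion_present,
    "solid": lambda e: e.solid_areas,
    "ascites": lambda e: e.ascites,
    "metastases": lambda e: e.metastases,
    "multilocular": lambda e: e.multilocular,
    "acoustic_shadows": lambda e: e.acoustic_shadows,
}


def map_orads(exam: Optional[UltrasoundExam], rules: Optional[list[dict]] = None) -> RiskScore:
    """Map an IOTA-described exam to an ORADS category via the shipped rule
    table; first matching rule wins.  Binary reading: positive iff 4-5."""
    if exam is None or not exam.scan_available:
        return RiskScore("orads", status="missing_inputs")
    if rules is None:
        rules = load_orads_table()
    for rule in rules:
        cond = rule["when"]
        ok = True
        for key, wanted in cond.items():
            if key == "papillation_count_ge":
                v = exam.papillation_count
                ok = v is not None and v >= wanted
            elif key == "papillation_count_le":
                v = exam.papillation_count
                ok = v is not None and v <= wanted
            elif key == "max_lesion_diameter_lt":
                v = exam.max_lesion_diameter
                ok = v is not None and v < wanted
            elif key == "max_lesion_diameter_ge":
                v = exam.max_lesion_diameter
                ok = v is not None and v >= wanted
            else:
                getter = _ORADS_FEATURE_GETTERS.get(key)
                if getter is None:
                    raise ConfigurationError(f"unknown ORADS rule feature {key!r}")
                v = getter(exam)
                ok = v is not None and bool(v) == bool(wanted)
            if not ok:
                break
        if ok:
            return RiskScore("orads", category=str(rule["category"]))
    return RiskScore("orads", status="missing_inputs")


# --------------------------------------------------------------------------
# Dichotomisation
# --------------------------------------------------------------------------


def dichotomize_score(score: RiskScore, threshold: Optional[float] = None) -> BinaryTestResult:
    """Turn a score into positive/negative/inconclusive/missing.

    Numeric scores: positive iff value is strictly greater than the
    threshold (the tie goes to negative, matching the ``>t`` / ``<t`` row
    convention of the source tables).  Simple rules: malignant -> positive,
    benign -> negative, inconclusive stays inconclusive.  ORADS: positive
    iff category 4 or 5.
    """
    if score.status == "missing_inputs":
        tid = score.model_id if threshold is None else f"{score.model_id}@{_tfmt(threshold)}"
        return BinaryTestResult(tid, "missing")
    if score.category is not None:
        if score.model_id == "simple_rules":
            state = {"malignant": "positive", "benign": "negative", "inconclusive": "inconclusive"}[
                score.category
            ]
            return BinaryTestResult("simple_rules", state)
        if score.model_id == "orads":
            return BinaryTestResult(
                "orads", "positive" if score.category in ("4", "5") else "negative"
            )
        raise ConfigurationError(f"no categorical dichotomisation rule for {score.model_id}")
    if threshold is None:
        raise ConfigurationError(f"{score.model_id} needs an explicit threshold")
    registered = DEFAULT_THRESHOLDS.get(score.model_id)
    if registered is not None and threshold not in registered:
        logger.info("threshold %s not in default registry for %s", threshold, score.model_id)
    state = "positive" if score.numeric_value > threshold else "negative"
    return BinaryTestResult(f"{score.model_id}@{_tfmt(threshold)}", state)


def _tfmt(t: float) -> str:
    return f"{t:g}"
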
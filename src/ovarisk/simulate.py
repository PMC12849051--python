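"""Synthetic cohort generator emulating a two-stage premenopausal referral study.

The generator states a world with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without patient data:

* two cohorts — a pre-protocol-change cohort (n=857, ovarian cancer
  prevalence 5.7%, mixed surgical and surveillance reference standard) and a
  post-change surgery-only cohort (n=354, prevalence 11.0%);
* a reference-class mix in which roughly 7% of non-cancer participants carry
  labels excluded from the primary outcome (borderline, secondary metastatic,
  uncertain behaviour, unresolved reference standard);
* class-conditional correlated log-normal CA 125 / HE4 levels, chosen so a
  CA 125 > 87 IU/mL rule lands near 55% sensitivity / 89% specificity —
  an emulation target, not an estimate;
* ultrasound B/M feature patterns tuned once so the simple-rules classifier
  returns roughly 15% inconclusive results overall (about 31% among cancers);
* class-dependent missingness (ultrasound missing more often among controls,
  as observed in surveillance-heavy recruitment).

Randomness comes from one seed with per-stage substreams (demographics,
class, markers, ultrasound, reference, missingness), so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import ParticipantRecord, ReferenceStandard, UltrasoundExam

__all__ = ["SyntheticConfig", "generate_cohort", "punch_missingness", "embed_true_model"]


# Reference classes: how each participant's disease status gets resolved.
# "biology" groups drive the marker/ultrasound distributions.
_CLASS_BIOLOGY = {
    "primary_invasive": "case",
    "secondary_metastatic": "case",
    "borderline": "intermediate",
    "uncertain_behaviour": "intermediate",
    "benign": "control",
    "normal": "control",
    "followup_negative": "control",
    "followup_pending": "control",
    "followup_cancer": "case",
    "missing": "control",
}

_DEFAULT_CLASS_MIX = {
    # proportions among non-primary-invasive participants; excluded-from-primary
    # classes total ~= 7%, emulating the observed exclusion fraction
    "benign": 0.370,
    "normal": 0.030,
    "followup_negative": 0.528,
    "borderline": 0.027,
    "secondary_metastatic": 0.012,
    "uncertain_behaviour": 0.002,
    "missing": 0.016,
    "followup_pending": 0.009,
    "followup_cancer": 0.006,
}

# ln-scale location/scale for CA125 (IU/mL) and HE4 (pmol/L), with correlation
_DEFAULT_MARKER_PARAMS = {
    "case": {"ca125": (4.65, 1.50), "he4": (4.65, 0.80), "rho": 0.5},
    "intermediate": {"ca125": (3.60, 1.20), "he4": (4.10, 0.50), "rho": 0.4},
    "control": {"ca125": (3.00, 1.20), "he4": (3.92, 0.30), "rho": 0.3},
}

_DEFAULT_ULTRASOUND_PARAMS = {
    # simple-rules presentation pattern: malignant-only / benign-only / mixed /
    # featureless. mixed+featureless -> inconclusive.
    "pattern": {
        "case": (0.52, 0.16, 0.22, 0.10),
        "intermediate": (0.30, 0.35, 0.25, 0.10),
        "control": (0.03, 0.83, 0.05, 0.09),
    },
    # U-score characteristics: multilocular, solid areas, metastases, ascites, bilateral
    "rmi_features": {
        "case": (0.45, 0.65, 0.15, 0.30, 0.25),
        "intermediate": (0.50, 0.35, 0.02, 0.10, 0.15),
        "control": (0.25, 0.12, 0.004, 0.04, 0.08),
    },
    "lesion_diameter_ln": {"case": (4.5, 0.5), "intermediate": (4.3, 0.5), "control": (4.0, 0.6)},
    "prop_solid_beta": {"case": (2.0, 1.5), "intermediate": (1.5, 3.0), "control": (1.0, 4.0)},
    "papillation_poisson": {"case": 0.9, "intermediate": 0.6, "control": 0.15},
    "locules_gt10": {"case": 0.15, "intermediate": 0.20, "control": 0.07},
    "acoustic_shadows": {"case": 0.05, "intermediate": 0.10, "control": 0.15},
    "featureless_lesion_prob": 0.4,  # featureless pattern: lesion present anyway?
}

_DEFAULT_MISSING_RATES = {
    # (case rate, control rate): ultrasound is missing far more often among
    # controls — surveillance-managed women skipped the study scan
    "ca125": (0.0, 0.005),
    "he4": (0.02, 0.062),
    "ultrasound": (0.04, 0.16),
    "adnex_extras": (0.02, 0.085),  # diameters/papillations absent given a scan
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_pre: int = 857
    n_post: int = 354
    prevalence_pre: float = 0.057
    prevalence_post: float = 0.110
    class_mix: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    marker_params: dict = field(default_factory=lambda: dict(_DEFAULT_MARKER_PARAMS))
    ultrasound_params: dict = field(default_factory=lambda: dict(_DEFAULT_ULTRASOUND_PARAMS))
    missing_rates: dict = field(default_factory=lambda: dict(_DEFAULT_MISSING_RATES))
    inconclusive_target: float = 0.15
    followup_fraction: float = 0.528  # share of cohort-1 non-cancers resolved by surveillance
    oncology_centre_rate: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre < 0 or self.n_post < 0:
            raise ValueError("cohort sizes must be nonnegative")
        for p in (self.prevalence_pre, self.prevalence_post):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must be in [0, 1]")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mix must sum to 1, got {total:.6f}")
        unknown = set(self.class_mix) - set(_CLASS_BIOLOGY)
        if unknown:
            raise ValueError(f"unknown reference classes in class_mix: {sorted(unknown)}")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("demographics", "class", "markers", "ultrasound", "reference", "missingness")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_markers(rng: np.random.Generator, params: dict, n: int) -> np.ndarray:
    mu = np.array([params["ca125"][0], params["he4"][0]])
    s1, s2 = params["ca125"][1], params["he4"][1]
    rho = params["rho"]
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    return np.exp(rng.multivariate_normal(mu, cov, size=n))


def _draw_features(rng: np.random.Generator, pattern: str, codes: Sequence[str], p_each: float):
    """Feature subset consistent with a simple-rules presentation pattern."""
    if pattern in ("none",):
        return frozenset()
    draws = rng.random(len(codes)) < p_each
    chosen = {c for c, d in zip(codes, draws) if d}
    if not chosen:  # pattern demands at least one feature
        chosen = {codes[rng.integers(len(codes))]}
    return frozenset(chosen)


def _make_exam(rng: np.random.Generator, biology: str, up: dict) -> UltrasoundExam:
    pat_probs = up["pattern"][biology]
    pattern = rng.choice(("malignant", "benign", "mixed", "featureless"), p=pat_probs)
    if pattern == "malignant":
        mal = _draw_features(rng, "some", ("M1", "M2", "M3", "M4", "M5"), 0.35)
        ben: frozenset = frozenset()
    elif pattern == "benign":
        ben = _draw_features(rng, "some", ("B1", "B2", "B3", "B4", "B5"), 0.35)
        mal = frozenset()
    elif pattern == "mixed":
        mal = _draw_features(rng, "some", ("M1", "M2", "M3", "M4", "M5"), 0.30)
        ben = _draw_features(rng, "some", ("B1", "B2", "B3", "B4", "B5"), 0.30)
    else:
        mal = ben = frozenset()

    lesion = True
    if pattern == "featureless" and rng.random() >= up["featureless_lesion_prob"]:
        lesion = False
    if not lesion:
        return UltrasoundExam(
            scan_available=True,
            lesion_present=False,
            max_lesion_diameter=None,
            max_solid_diameter=None,
            multilocular=False,
            solid_areas=False,
            bilateral=False,
            ascites=False,
            metastases=False,
            more_than_10_locules=False,
            papillation_count=0,
            acoustic_shadows=False,
            benign_features=ben,
            malignant_features=mal,
        )

    mrates = up["rmi_features"][biology]
    multiloc, solid, mets, ascites, bilat = (rng.random(5) < np.array(mrates)).tolist()
    mu, sd = up["lesion_diameter_ln"][biology]
    diameter = float(np.exp(rng.normal(mu, sd)))
    if solid:
        a, b = up["prop_solid_beta"][biology]
        prop = float(rng.beta(a, b))
    else:
        prop = 0.0
    pap = int(min(rng.poisson(up["papillation_poisson"][biology]), 4))
    gt10 = bool(multiloc and rng.random() < up["locules_gt10"][biology] / 0.25)
    shadows = bool(rng.random() < up["acoustic_shadows"][biology])
    return UltrasoundExam(
        scan_available=True,
        lesion_present=True,
        max_lesion_diameter=round(diameter, 1),
        max_solid_diameter=round(diameter * prop, 1),
        multilocular=multiloc,
        solid_areas=solid,
        bilateral=bilat,
        ascites=ascites,
        metastases=mets,
        more_than_10_locules=gt10,
        papillation_count=pap,
        acoustic_shadows=shadows,
        benign_features=ben,
        malignant_features=mal,
    )


def _make_reference(rng: np.random.Generator, ref_class: str) -> ReferenceStandard:
    if ref_class == "primary_invasive":
        stage = rng.choice([1, 2, 3, 4, 0], p=(0.50, 0.07, 0.27, 0.01, 0.15))
        return ReferenceStandard(
            source="surgery" if rng.random() < 0.92 else "biopsy",
            histology_category="primary_invasive",
            figo_stage=None if stage == 0 else int(stage),
            followup_cancer_diagnosis="unknown",
        )
    if ref_class in ("benign", "normal", "borderline", "secondary_metastatic", "uncertain_behaviour"):
        return ReferenceStandard(source="surgery", histology_category=ref_class)
    if ref_class == "missing":
        return ReferenceStandard(source="surgery", histology_category="missing")
    if ref_class == "followup_negative":
        return ReferenceStandard(
            source="follow_up", histology_category="no_histology", followup_cancer_diagnosis="no"
        )
    if ref_class == "followup_pending":
        return ReferenceStandard(
            source="follow_up", histology_category="no_histology", followup_cancer_diagnosis="unknown"
        )
    if ref_class == "followup_cancer":
        return ReferenceStandard(
            source="follow_up", histology_category="no_histology", followup_cancer_diagnosis="yes"
        )
    raise ValueError(f"unknown reference class {ref_class!r}")


def generate_cohort(config: SyntheticConfig) -> list[ParticipantRecord]:
    """Draw a full two-cohort synthetic study population.

    Stage order: disease class first, then markers (correlated log-normals per
    class), then the ultrasound exam (per-class feature patterns), then the
    reference standard, then missingness.  Reproducible for a fixed seed.
    """
    rngs = _streams(config.seed)
    records: list[ParticipantRecord] = []

    mix_classes = list(config.class_mix)
    mix_probs = np.array([config.class_mix[c] for c in mix_classes])

    for cohort_tag, n, prev in (
        ("pre_change", config.n_pre, config.prevalence_pre),
        ("post_change", config.n_post, config.prevalence_post),
    ):
        for i in range(n):
            pid = f"{'P' if cohort_tag == 'pre_change' else 'Q'}{i:05d}"
            is_case = bool(rngs["class"].random() < prev)
            if is_case:
                ref_class = "primary_invasive"
            else:
                ref_class = str(rngs["class"].choice(mix_classes, p=mix_probs))
                if cohort_tag == "post_change" and ref_class.startswith("followup"):
                    # the post-change cohort is surgery-only: surveillance
                    # resolution does not occur there
                    ref_class = "benign"
            biology = _CLASS_BIOLOGY[ref_class]

            age = float(np.clip(rngs["demographics"].normal(42.0, 8.0), 18.0, 50.4))
            centre = "oncology" if rngs["demographics"].random() < config.oncology_centre_rate else "non_oncology"
            ca125, he4 = _draw_markers(rngs["markers"], config.marker_params[biology], 1)[0]
            exam = _make_exam(rngs["ultrasound"], biology, config.ultrasound_params)
            ref = _make_reference(rngs["reference"], ref_class)
            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    age=round(age, 1),
                    menstruated_last_12m="yes" if age < 50 else "unknown",
                    vaginal_bleeding_history="yes",
                    menopausal_status="premenopausal",
                    ca125=round(float(ca125), 1),
                    he4=round(float(he4), 1),
                    ultrasound=exam,
                    centre_type=centre,
                    cohort_tag=cohort_tag,
                    reference=ref,
                )
            )

    return punch_missingness(
        records, config.missing_rates, mechanism="mar_on_class", rng=rngs["missingness"]
    )


def _rate_for(rates, is_case: bool, mechanism: str) -> float:
    if isinstance(rates, (tuple, list)):
        case_rate, control_rate = rates
    else:
        case_rate = control_rate = float(rates)
    if mechanism == "mcar":
        return (case_rate + control_rate) / 2 if isinstance(rates, (tuple, list)) else case_rate
    return case_rate if is_case else control_rate


def punch_missingness(
    cohort: Sequence[ParticipantRecord],
    rates: dict,
    mechanism: str = "mar_on_class",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[ParticipantRecord]:
    """Remove values at random: MCAR, or MAR-on-class with per-class rates.

    ``rates`` maps variable names (``ca125``, ``he4``, ``ultrasound``,
    ``adnex_extras``) to a scalar rate or a ``(case_rate, control_rate)``
    pair; a "case" here is a participant whose histology category is
    primary invasive.
    """
    if mechanism not in ("mcar", "mar_on_class"):
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[ParticipantRecord] = []
    n_punched = 0
    for rec in cohort:
        is_case = rec.reference.histology_category == "primary_invasive"
        changes: dict = {}
        for var, var_rates in rates.items():
            rate = _rate_for(var_rates, is_case, mechanism)
            if rate <= 0 or rng.random() >= rate:
                continue
            n_punched += 1
            if var in ("ca125", "he4"):
                changes[var] = None
            elif var == "ultrasound":
                changes["ultrasound"] = None
            elif var == "adnex_extras":
                us = changes.get("ultrasound", rec.ultrasound)
                if us is not None:
                    changes["ultrasound"] = replace(
                        us, max_lesion_diameter=None, max_solid_diameter=None, papillation_count=None
                    )
            else:
                raise ValueError(f"unknown variable {var!r} in missingness rates")
        out.append(replace(rec, **changes) if changes else rec)
    return out


def embed_true_model(
    n: int,
    risk_function: Callable[[ParticipantRecord], float],
    seed: int = 0,
    config: Optional[SyntheticConfig] = None,
) -> tuple[list[ParticipantRecord], np.ndarray]:
    """Cohort whose outcome is Bernoulli of a known per-participant risk.

    Covariates are drawn from the configured *control* distributions (a
    neutral background), the supplied risk function is evaluated on each
    record, and the reference standard is set to primary invasive cancer with
    that probability — so downstream calibration-slope and C-index estimates
    have known truth.  Returns the records and the true risks.
    """
    config = config or SyntheticConfig(seed=seed)
    rngs = _streams(seed)
    records: list[ParticipantRecord] = []
    risks = np.empty(n)
    for i in range(n):
        age = float(np.clip(rngs["demographics"].normal(42.0, 8.0), 18.0, 49.9))
        ca125, he4 = _draw_markers(rngs["markers"], config.marker_params["control"], 1)[0]
        exam = _make_exam(rngs["ultrasound"], "control", config.ultrasound_params)
        rec = ParticipantRecord(
            participant_id=f"T{i:06d}",
            age=round(age, 1),
            menstruated_last_12m="yes",
            menopausal_status="premenopausal",
            ca125=round(float(ca125), 1),
            he4=round(float(he4), 1),
            ultrasound=exam,
            centre_type="non_oncology",
            cohort_tag="pre_change",
        )
        p = float(risk_function(rec))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"risk function returned {p}, outside [0, 1]")
        risks[i] = p
        is_case = rngs["class"].random() < p
        rec = replace(
            rec,
            reference=ReferenceStandard(
                source="surgery",
                histology_category="primary_invasive" if is_case else "benign",
            ),
        )
        records.append(rec)
    return records, risks
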
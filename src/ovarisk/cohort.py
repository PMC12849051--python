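"""Participant data model, CSV I/O, menopausal classification and outcome labels.

The unit of analysis is one woman referred to secondary care with non-specific
symptoms and an abnormal CA 125 or ultrasound result.  Each record carries the
serum markers (CA 125 in IU/mL, HE4 in pmol/L), the ultrasound examination
described in IOTA terminology, and the reference standard (histology from
surgery/biopsy/cytology, or 12-month surveillance for conservatively managed
women).

Units are fixed: CA 125 IU/mL, HE4 pmol/L, diameters mm.  Missing values in
CSV are empty cells or the literal ``NA``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UltrasoundExam",
    "ReferenceStandard",
    "ParticipantRecord",
    "OutcomeDefinition",
    "OUTCOME_DEFINITIONS",
    "HISTOLOGY_CATEGORIES",
    "SchemaError",
    "IntegrityError",
    "ClassificationError",
    "classify_menopause",
    "derive_outcome",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "filter_cohort",
    "missingness_report",
]


class SchemaError(ValueError):
    """Input file does not match the documented column schema."""


class IntegrityError(ValueError):
    """Cross-record consistency violation (e.g. duplicate participant ids)."""


class ClassificationError(ValueError):
    """Menopausal status cannot be determined from the available inputs."""


HISTOLOGY_CATEGORIES = (
    "primary_invasive",
    "secondary_metastatic",
    "borderline",
    "uncertain_behaviour",
    "benign",
    "normal",
    "no_histology",
    "missing",
)

BENIGN_FEATURES = ("B1", "B2", "B3", "B4", "B5")
MALIGNANT_FEATURES = ("M1", "M2", "M3", "M4", "M5")


@dataclass
class UltrasoundExam:
    """One IOTA-terminology ultrasound examination.

    The five RMI U-score characteristics (multilocular cyst, solid areas,
    metastases, ascites, bilateral lesions), the ADNEX predictors (diameters,
    >10 locules, papillation count, acoustic shadows) and the ten simple-rules
    B/M features are all carried explicitly; flags are True/False, or None
    when not assessed.
    """

    scan_available: bool = True
    lesion_present: Optional[bool] = None
    max_lesion_diameter: Optional[float] = None  # mm
    max_solid_diameter: Optional[float] = None  # mm
    multilocular: Optional[bool] = None
    solid_areas: Optional[bool] = None
    bilateral: Optional[bool] = None
    ascites: Optional[bool] = None
    metastases: Optional[bool] = None
    more_than_10_locules: Optional[bool] = None
    papillation_count: Optional[int] = None
    acoustic_shadows: Optional[bool] = None
    benign_features: Optional[frozenset[str]] = None
    malignant_features: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.benign_features is not None:
            bad = set(self.benign_features) - set(BENIGN_FEATURES)
            if bad:
                raise ValueError(f"unknown benign feature codes: {sorted(bad)}")
            self.benign_features = frozenset(self.benign_features)
        if self.malignant_features is not None:
            bad = set(self.malignant_features) - set(MALIGNANT_FEATURES)
            if bad:
                raise ValueError(f"unknown malignant feature codes: {sorted(bad)}")
            self.malignant_features = frozenset(self.malignant_features)
        if (
            self.max_solid_diameter is not None
            and self.max_lesion_diameter is not None
            and self.max_solid_diameter > self.max_lesion_diameter
        ):
            raise ValueError(
                "max_solid_diameter exceeds max_lesion_diameter "
                f"({self.max_solid_diameter} > {self.max_lesion_diameter})"
            )


@dataclass
class ReferenceStandard:
    """Disease status source: histology if operated/biopsied, else surveillance."""

    source: Literal["surgery", "biopsy", "cytology", "follow_up", "none"] = "none"
    histology_category: str = "missing"
    figo_stage: Optional[int] = None  # metadata only; never affects labels
    followup_cancer_diagnosis: Literal["yes", "no", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        if self.histology_category not in HISTOLOGY_CATEGORIES:
            raise ValueError(f"unknown histology category {self.histology_category!r}")


@dataclass
class ParticipantRecord:
    participant_id: str
    age: float  # years
    menstruated_last_12m: Literal["yes", "no", "unknown"] = "unknown"
    vaginal_bleeding_history: Literal["yes", "no", "unknown"] = "unknown"
    menopausal_status: Optional[str] = None  # derived; premenopausal/postmenopausal
    ca125: Optional[float] = None  # IU/mL
    he4: Optional[float] = None  # pmol/L
    ultrasound: Optional[UltrasoundExam] = None
    centre_type: Literal["oncology", "non_oncology"] = "non_oncology"
    cohort_tag: Literal["pre_change", "post_change"] = "pre_change"
    reference: ReferenceStandard = field(default_factory=ReferenceStandard)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        for name in ("ca125", "he4"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


def classify_menopause(
    age: float,
    menstruated_last_12m: str = "unknown",
    vaginal_bleeding_history: str = "unknown",
) -> str:
    """Classify a woman as premenopausal or postmenopausal.

    Rule table (age criterion <50 vs >=51 combined with menstruation in the
    past 12 months):

    ==========  ===============  ===========================================
    age         menstruated      status
    ==========  ===============  ===========================================
    < 50        yes              premenopausal
    >= 51       no               postmenopausal
    otherwise   (perimenopausal) re-categorised by vaginal bleeding history:
                                 bleeding in past 12 months -> premenopausal,
                                 no bleeding -> postmenopausal
    ==========  ===============  ===========================================

    The perimenopausal band covers ages in [50, 51), unknown menstruation
    status, and age/menstruation disagreement.

    Raises
    ------
    ClassificationError
        If the record falls in the perimenopausal band and the bleeding
        history is also unknown.
    """
    if age is None or (isinstance(age, float) and math.isnan(age)):
        raise ClassificationError("age is required for menopausal classification")
    if age < 50 and menstruated_last_12m == "yes":
        return "premenopausal"
    if age >= 51 and menstruated_last_12m == "no":
        return "postmenopausal"
    if vaginal_bleeding_history == "yes":
        return "premenopausal"
    if vaginal_bleeding_history == "no":
        return "postmenopausal"
    raise ClassificationError(
        "perimenopausal record (age %.1f, menstruated=%s) with unknown bleeding history"
        % (age, menstruated_last_12m)
    )


@dataclass(frozen=True)
class OutcomeDefinition:
    """Maps histology categories to positive/negative/excluded labels.

    The three named definitions:

    * ``primary`` — primary invasive ovarian cancer vs benign/normal (or
      negative surveillance); borderline, secondary metastatic, uncertain
      behaviour and unresolved records are excluded.
    * ``secondary_any_cancer`` — any cancer (primary invasive, secondary
      metastatic, borderline, uncertain behaviour) vs everything else;
      unresolved reference standards count as negative so every participant
      contributes.
    * ``secondary_borderline_as_benign`` — as the secondary definition but
      with borderline tumours grouped with benign.
    """

    name: str
    positive_categories: frozenset[str]
    negative_categories: frozenset[str]
    excluded_categories: frozenset[str]

    def __post_init__(self) -> None:
        sets = (self.positive_categories, self.negative_categories, self.excluded_categories)
        union: set[str] = set()
        total = 0
        for s in sets:
            union |= s
            total += len(s)
        if total != len(union) or union != set(HISTOLOGY_CATEGORIES):
            raise ValueError(
                f"outcome definition {self.name!r} must partition all histology categories"
            )


OUTCOME_DEFINITIONS: dict[str, OutcomeDefinition] = {
    "primary": OutcomeDefinition(
        name="primary",
        positive_categories=frozenset({"primary_invasive"}),
        negative_categories=frozenset({"benign", "normal"}),
        excluded_categories=frozenset(
            {"borderline", "secondary_metastatic", "uncertain_behaviour", "no_histology", "missing"}
        ),
    ),
    "secondary_any_cancer": OutcomeDefinition(
        name="secondary_any_cancer",
        positive_categories=frozenset(
            {"primary_invasive", "secondary_metastatic", "borderline", "uncertain_behaviour"}
        ),
        negative_categories=frozenset({"benign", "normal", "no_histology", "missing"}),
        excluded_categories=frozenset(),
    ),
    "secondary_borderline_as_benign": OutcomeDefinition(
        name="secondary_borderline_as_benign",
        positive_categories=frozenset(
            {"primary_invasive", "secondary_metastatic", "uncertain_behaviour"}
        ),
        negative_categories=frozenset({"borderline", "benign", "normal", "no_histology", "missing"}),
        excluded_categories=frozenset(),
    ),
}


def derive_outcome(reference: ReferenceStandard, definition: OutcomeDefinition | str) -> str:
    """Return ``positive`` / ``negative`` / ``excluded`` for one participant.

    Unresolved histology (``no_histology`` or ``missing``) is resolved through
    the 12-month surveillance flag before the category sets apply: a completed
    negative follow-up is a negative under every definition; a cancer detected
    at follow-up without confirmatory histology cannot be attributed to the
    ovary and is excluded under the primary definition (positive under the
    any-cancer definitions); follow-up still pending leaves the category as-is
    (excluded under the primary definition).
    """
    if isinstance(definition, str):
        try:
            definition = OUTCOME_DEFINITIONS[definition]
        except KeyError:
            raise ValueError(f"unknown outcome definition {definition!r}") from None
    cat = reference.histology_category
    if cat not in HISTOLOGY_CATEGORIES:
        raise ValueError(f"unknown histology category {cat!r}")
    if cat in ("no_histology", "missing"):
        if reference.followup_cancer_diagnosis == "no":
            return "negative"
        if reference.followup_cancer_diagnosis == "yes":
            # cancer of unverified origin: never a primary-invasive positive
            return "excluded" if definition.name == "primary" else "positive"
        # follow-up pending/unknown
        if definition.name == "primary":
            return "excluded"
    if cat in definition.positive_categories:
        return "positive"
    if cat in definition.negative_categories:
        return "negative"
    return "excluded"


# --------------------------------------------------------------------------
# CSV schema
# --------------------------------------------------------------------------

MANDATORY_COLUMNS = ("participant_id", "age", "cohort_tag")

_BOOL_US_COLS = (
    "lesion_present",
    "multilocular",
    "solid_areas",
    "bilateral",
    "ascites",
    "metastases",
    "more_than_10_locules",
    "acoustic_shadows",
)

COLUMN_DICTIONARY = {
    "participant_id": "opaque identifier, unique per row",
    "age": "age in years",
    "menstruated_last_12m": "yes/no/unknown",
    "vaginal_bleeding_history": "yes/no/unknown",
    "menopausal_status": "premenopausal/postmenopausal (derived; optional on input)",
    "ca125": "serum CA 125, IU/mL",
    "he4": "serum HE4, pmol/L",
    "centre_type": "oncology/non_oncology",
    "cohort_tag": "pre_change/post_change",
    "us_scan_available": "0/1",
    "us_lesion_present": "0/1",
    "us_max_lesion_diameter": "mm",
    "us_max_solid_diameter": "mm",
    "us_multilocular": "0/1",
    "us_solid_areas": "0/1",
    "us_bilateral": "0/1",
    "us_ascites": "0/1",
    "us_metastases": "0/1",
    "us_more_than_10_locules": "0/1",
    "us_papillation_count": "integer 0-4 (4 = more than 3)",
    "us_acoustic_shadows": "0/1",
    "us_benign_features": "semicolon-joined subset of B1..B5",
    "us_malignant_features": "semicolon-joined subset of M1..M5",
    "ref_source": "surgery/biopsy/cytology/follow_up/none",
    "histology_category": "; ".join(HISTOLOGY_CATEGORIES),
    "figo_stage": "1-4, metadata only",
    "followup_cancer_diagnosis": "yes/no/unknown",
}

_NA_STRINGS = ("", "NA")


def _parse_float(value, column: str, pid: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in _NA_STRINGS:
        return None
    try:
        return float(s)
    except ValueError:
        logger.warning("unparseable %s value %r for participant %s -> missing", column, value, pid)
        return None


def _parse_flag(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in _NA_STRINGS:
        return None
    if s in ("1", "1.0", "yes", "True", "true"):
        return True
    if s in ("0", "0.0", "no", "False", "false"):
        return False
    return None


def _parse_cat(value, default: str = "unknown") -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    s = str(value).strip()
    return default if s in _NA_STRINGS else s


def _parse_features(value, prefix: str) -> Optional[frozenset[str]]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in _NA_STRINGS:
        return None
    if s == "-":  # assessed, none present
        return frozenset()
    return frozenset(tok for tok in s.split(";") if tok)


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Build ParticipantRecords from a schema-conformant DataFrame."""
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    ids = df["participant_id"].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique()[:5]
        raise IntegrityError(f"duplicate participant_id values: {list(dups)}")

    records = []
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        age = _parse_float(row["age"], "age", pid)
        if age is None:
            raise SchemaError(f"participant {pid}: age is mandatory")
        us = None
        if _parse_flag(row.get("us_scan_available")) is not False and any(
            c in df.columns for c in ("us_lesion_present", "us_benign_features")
        ):
            sd = _parse_float(row.get("us_max_solid_diameter"), "us_max_solid_diameter", pid)
            ld = _parse_float(row.get("us_max_lesion_diameter"), "us_max_lesion_diameter", pid)
            pap = _parse_float(row.get("us_papillation_count"), "us_papillation_count", pid)
            us = UltrasoundExam(
                scan_available=_parse_flag(row.get("us_scan_available")) is not False,
                lesion_present=_parse_flag(row.get("us_lesion_present")),
                max_lesion_diameter=ld,
                max_solid_diameter=sd,
                multilocular=_parse_flag(row.get("us_multilocular")),
                solid_areas=_parse_flag(row.get("us_solid_areas")),
                bilateral=_parse_flag(row.get("us_bilateral")),
                ascites=_parse_flag(row.get("us_ascites")),
                metastases=_parse_flag(row.get("us_metastases")),
                more_than_10_locules=_parse_flag(row.get("us_more_than_10_locules")),
                papillation_count=None if pap is None else int(pap),
                acoustic_shadows=_parse_flag(row.get("us_acoustic_shadows")),
                benign_features=_parse_features(row.get("us_benign_features"), "B"),
                malignant_features=_parse_features(row.get("us_malignant_features"), "M"),
            )
        figo = _parse_float(row.get("figo_stage"), "figo_stage", pid)
        ref = ReferenceStandard(
            source=_parse_cat(row.get("ref_source"), "none"),
            histology_category=_parse_cat(row.get("histology_category"), "missing"),
            figo_stage=None if figo is None else int(figo),
            followup_cancer_diagnosis=_parse_cat(row.get("followup_cancer_diagnosis")),
        )
        status = _parse_cat(row.get("menopausal_status"), "")
        records.append(
            ParticipantRecord(
                participant_id=pid,
                age=age,
                menstruated_last_12m=_parse_cat(row.get("menstruated_last_12m")),
                vaginal_bleeding_history=_parse_cat(row.get("vaginal_bleeding_history")),
                menopausal_status=status or None,
                ca125=_parse_float(row.get("ca125"), "ca125", pid),
                he4=_parse_float(row.get("he4"), "he4", pid),
                ultrasound=us,
                centre_type=_parse_cat(row.get("centre_type"), "non_oncology"),
                cohort_tag=_parse_cat(row.get("cohort_tag"), "pre_change"),
                reference=ref,
            )
        )
    return records


def read_cohort(path, schema_version: str = "1") -> list[ParticipantRecord]:
    """Read a cohort CSV (UTF-8, one row per participant) into records.

    Unparseable numeric cells become missing with a logged warning; missing
    mandatory columns raise :class:`SchemaError`; duplicate participant ids
    raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_records(df)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, frozenset):
        return ";".join(sorted(value)) if value else "-"
    if isinstance(value, float) and value == int(value):
        return repr(value)
    return str(value)


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into the documented CSV schema (string cells)."""
    rows = []
    for r in records:
        us = r.ultrasound
        row = {
            "participant_id": r.participant_id,
            "age": _fmt(r.age),
            "menstruated_last_12m": r.menstruated_last_12m,
            "vaginal_bleeding_history": r.vaginal_bleeding_history,
            "menopausal_status": r.menopausal_status or "",
            "ca125": _fmt(r.ca125),
            "he4": _fmt(r.he4),
            "centre_type": r.centre_type,
            "cohort_tag": r.cohort_tag,
            "us_scan_available": _fmt(us.scan_available) if us else "0",
            "ref_source": r.reference.source,
            "histology_category": r.reference.histology_category,
            "figo_stage": _fmt(r.reference.figo_stage),
            "followup_cancer_diagnosis": r.reference.followup_cancer_diagnosis,
        }
        if us is not None:
            row.update(
                {
                    "us_lesion_present": _fmt(us.lesion_present),
                    "us_max_lesion_diameter": _fmt(us.max_lesion_diameter),
                    "us_max_solid_diameter": _fmt(us.max_solid_diameter),
                    "us_multilocular": _fmt(us.multilocular),
                    "us_solid_areas": _fmt(us.solid_areas),
                    "us_bilateral": _fmt(us.bilateral),
                    "us_ascites": _fmt(us.ascites),
                    "us_metastases": _fmt(us.metastases),
                    "us_more_than_10_locules": _fmt(us.more_than_10_locules),
                    "us_papillation_count": _fmt(us.papillation_count),
                    "us_acoustic_shadows": _fmt(us.acoustic_shadows),
                    "us_benign_features": _fmt(us.benign_features),
                    "us_malignant_features": _fmt(us.malignant_features),
                }
            )
        rows.append(row)
    cols = [c for c in COLUMN_DICTIONARY if any(c in r for r in rows)]
    return pd.DataFrame(rows, columns=cols).fillna("")


def write_cohort(records: Iterable[ParticipantRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def filter_cohort(
    records: Sequence[ParticipantRecord],
    cohort_selector: Literal["pre_change", "post_change", "combined"] = "combined",
) -> list[ParticipantRecord]:
    """Select the pre-protocol-change cohort, the post-change cohort, or both."""
    if cohort_selector == "combined":
        out = list(records)
    elif cohort_selector in ("pre_change", "post_change"):
        out = [r for r in records if r.cohort_tag == cohort_selector]
    else:
        raise ValueError(f"unknown cohort selector {cohort_selector!r}")
    logger.info("filter_cohort(%s): %d of %d records", cohort_selector, len(out), len(records))
    if not out:
        warnings.warn(f"cohort selector {cohort_selector!r} matched no records", stacklevel=2)
    return out


def missingness_report(records: Sequence[ParticipantRecord]) -> dict:
    """Per-column missingness counts, as a JSON-serialisable data-quality report."""
    df = records_to_frame(records)
    n = len(df)
    report = {
        "n_records": n,
        "columns": {
            col: {"n_missing": int((df[col].astype(str).isin(_NA_STRINGS)).sum())}
            for col in df.columns
        },
    }
    return report
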
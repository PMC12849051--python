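"""End-to-end orchestration: cohort -> scores -> accuracy report.

`run_pipeline` reproduces the layout of a head-to-head diagnostic accuracy
analysis from one config object: per outcome definition it emits a table of
conclusive-result counts, sensitivity/specificity/PPV/NPV with exact CIs, a
C-index per continuous model, and paired McNemar comparisons of every test
against the comparator (RMI 1 at 250 by default) with Bonferroni-adjusted
significance flags, plus ROC and calibration-decile data files and a run
manifest.

`replicate_printed_table` re-derives every derivable accuracy cell of the
published cohort-1 table from its printed classification counts (shipped as a
transcribed CSV fixture) and diffs the recomputation against the printed
values at the table's 1-decimal precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .accuracy import (
    AccuracyEstimate,
    TwoByTwo,
    accuracy_metrics,
    adjust_multiplicity,
    build_two_by_two,
    mcnemar_paired,
)
from .cohort import OUTCOME_DEFINITIONS, ParticipantRecord, derive_outcome, filter_cohort, read_cohort
from .models import (
    DEFAULT_THRESHOLDS,
    CoefficientSet,
    compute_adnex,
    compute_rmi,
    compute_roma,
    compute_simple_rules,
    compute_simple_rules_risk,
    compute_u_score,
    default_registry,
    dichotomize_score,
    load_orads_table,
    map_orads,
    RiskScore,
)
from .performance import c_index, calibration_deciles, calibration_slope, roc_points

__all__ = [
    "PipelineConfig",
    "score_cohort",
    "binary_results",
    "run_pipeline",
    "replicate_printed_table",
    "CONTINUOUS_MODELS",
]

CONTINUOUS_MODELS = ("rmi1", "roma", "adnex", "srrisk", "ca125")
PROBABILITY_MODELS = ("roma", "adnex", "srrisk")


@dataclass
class PipelineConfig:
    cohort_csv: Optional[str] = None  # one of cohort_csv / records / synthetic
    records: Optional[Sequence[ParticipantRecord]] = None
    synthetic: Optional[object] = None  # SyntheticConfig
    cohort_selector: str = "pre_change"
    outcomes: tuple[str, ...] = ("primary",)
    comparator: str = "rmi1@250"
    thresholds: Mapping[str, tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    include_simple_rules: bool = True
    include_orads: bool = False  # post hoc analysis, off by default
    inconclusive_policy: str = "exclude"
    coefficient_registry: Optional[Mapping[str, CoefficientSet]] = None
    output_dir: Optional[str] = None
    seed: int = 0


def score_cohort(
    records: Sequence[ParticipantRecord],
    registry: Optional[Mapping[str, CoefficientSet]] = None,
    orads_rules: Optional[list] = None,
) -> pd.DataFrame:
    """Score every model for every participant.

    Returns a DataFrame indexed by participant id with numeric score columns
    (``rmi1``, ``roma``, ``adnex``, ``srrisk``, ``ca125``; NaN = missing
    inputs) and categorical columns (``simple_rules``, ``orads``; empty
    string = missing inputs).
    """
    registry = registry or default_registry()
    orads_rules = orads_rules or load_orads_table()
    rows = []
    for r in records:
        status = r.menopausal_status or "premenopausal"
        u = compute_u_score(r.ultrasound)
        rmi = compute_rmi(r.ca125, u, status)
        roma = compute_roma(r.ca125, r.he4, status, registry["roma"])
        adnex = compute_adnex(r.age, r.ca125, r.ultrasound, r.centre_type, registry["adnex"])
        srr = compute_simple_rules_risk(r.ultrasound, r.centre_type, registry["srrisk"])
        sr = compute_simple_rules(r.ultrasound)
        orads = map_orads(r.ultrasound, orads_rules)
        rows.append(
            {
                "participant_id": r.participant_id,
                "rmi1": _num(rmi),
                "roma": _num(roma),
                "adnex": _num(adnex),
                "srrisk": _num(srr),
                "ca125": r.ca125 if r.ca125 is not None else np.nan,
                "simple_rules": sr.category or "",
                "orads": orads.category or "",
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def _num(score: RiskScore) -> float:
    return score.numeric_value if score.status == "computed" else np.nan


def binary_results(
    scores: pd.DataFrame,
    thresholds: Mapping[str, tuple[float, ...]],
    include_simple_rules: bool = True,
    include_orads: bool = False,
) -> dict[str, dict[str, str]]:
    """Dichotomise the score table into per-test result maps (pid -> state)."""
    out: dict[str, dict[str, str]] = {}
    for model, ts in thresholds.items():
        for t in ts:
            tid = f"{model}@{t:g}"
            col = scores[model]
            out[tid] = {
                pid: ("missing" if math.isnan(v) else ("positive" if v > t else "negative"))
                for pid, v in col.items()
            }
    if include_simple_rules and "simple_rules" in scores:
        m = {"malignant": "positive", "benign": "negative", "inconclusive": "inconclusive", "": "missing"}
        out["simple_rules"] = {pid: m[v] for pid, v in scores["simple_rules"].items()}
    if include_orads and "orads" in scores:
        out["orads"] = {
            pid: ("missing" if v == "" else ("positive" if v in ("4", "5") else "negative"))
            for pid, v in scores["orads"].items()
        }
    return out


@dataclass
class ReportBundle:
    accuracy_tables: dict[str, pd.DataFrame]  # per outcome definition
    roc_data: dict[str, pd.DataFrame]  # per model, primary outcome
    calibration_data: dict[str, pd.DataFrame]
    manifest: dict
    scores: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Generate/load -> score -> evaluate -> report."""
    if config.records is not None:
        records = list(config.records)
    elif config.cohort_csv is not None:
        records = read_cohort(config.cohort_csv)
    elif config.synthetic is not None:
        from .simulate import generate_cohort

        records = generate_cohort(config.synthetic)
    else:
        raise ValueError("PipelineConfig needs one of records / cohort_csv / synthetic")
    records = filter_cohort(records, config.cohort_selector)
    registry = config.coefficient_registry or default_registry()
    scores = score_cohort(records, registry)
    results = binary_results(
        scores, config.thresholds, config.include_simple_rules, config.include_orads
    )
    comparator = config.comparator
    if comparator not in results:
        raise ValueError(f"comparator {comparator!r} not in threshold registry")

    accuracy_tables: dict[str, pd.DataFrame] = {}
    roc_data: dict[str, pd.DataFrame] = {}
    calibration_data: dict[str, pd.DataFrame] = {}

    for outcome_name in config.outcomes:
        outcomes = {r.participant_id: derive_outcome(r.reference, outcome_name) for r in records}
        rows = []
        test_ids = [t for t in results if t != comparator]
        comparisons = {}
        for tid in test_ids:
            try:
                comparisons[tid] = mcnemar_paired(
                    results[tid], results[comparator], outcomes, test_a=tid, test_b=comparator
                )
            except ValueError:
                comparisons[tid] = None
        flags, alpha = adjust_multiplicity(
            [c.p_value_sens if c else None for c in comparisons.values()], max(len(comparisons), 1)
        )
        sens_flags = dict(zip(comparisons, flags))

        cix = {}
        y = pd.Series(outcomes)
        mask = y.isin(["positive", "negative"])
        ybin = (y[mask] == "positive").astype(int)
        for model in CONTINUOUS_MODELS:
            s = scores.loc[ybin.index, model]
            cix[model] = c_index(s.values, ybin.values)

        for tid in results:
            table = build_two_by_two(
                results[tid], outcomes, config.inconclusive_policy, tid, outcome_name
            )
            mets = accuracy_metrics(table)
            model = tid.split("@")[0]
            comp = comparisons.get(tid)
            row = {
                "test_id": tid,
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
                "n_missing": table.n_missing_test,
                "n_inconclusive": table.n_inconclusive,
                "n_with_result": table.n_conclusive + table.n_inconclusive,
            }
            for name, est in mets.items():
                row[name] = _pct(est.point)
                row[f"{name}_lo"] = _pct(est.ci_low)
                row[f"{name}_hi"] = _pct(est.ci_high)
            ci = cix.get(model)
            if ci is not None and ci.defined:
                row["c_index"] = round(ci.estimate, 2)
                row["c_index_lo"] = round(ci.ci_low, 2)
                row["c_index_hi"] = round(ci.ci_high, 2)
            if comp is not None:
                row["delta_sens"] = _pct(comp.delta_sensitivity)
                row["delta_sens_lo"] = _pct(comp.delta_sensitivity_ci[0])
                row["delta_sens_hi"] = _pct(comp.delta_sensitivity_ci[1])
                row["p_sens"] = comp.p_value_sens
                row["delta_spec"] = _pct(comp.delta_specificity)
                row["delta_spec_lo"] = _pct(comp.delta_specificity_ci[0])
                row["delta_spec_hi"] = _pct(comp.delta_specificity_ci[1])
                row["p_spec"] = comp.p_value_spec
                row["n_common"] = comp.n_common
                row["significant_sens"] = sens_flags.get(tid)
                row["adjusted_alpha"] = alpha
            rows.append(row)
        accuracy_tables[outcome_name] = pd.DataFrame(rows).set_index("test_id")

        if outcome_name == config.outcomes[0]:
            for model in CONTINUOUS_MODELS:
                s = scores.loc[ybin.index, model]
                ok = ~s.isna()
                if ybin[ok].nunique() < 2:
                    continue
                curve = roc_points(s[ok].values, ybin[ok].values)
                roc_data[model] = pd.DataFrame(
                    {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
                )
                if model in PROBABILITY_MODELS:
                    rep = calibration_deciles(s[ok].values / 100.0, ybin[ok].values)
                    slope = calibration_slope(s[ok].values / 100.0, ybin[ok].values)
                    g = rep.groups.copy()
                    g.attrs["slope"] = slope.slope
                    g.attrs["slope_ci"] = slope.slope_ci
                    g.attrs["intercept"] = slope.intercept
                    calibration_data[model] = g

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "cohort_selector": config.cohort_selector,
        "n_records": len(records),
        "outcomes": list(config.outcomes),
        "comparator": comparator,
        "thresholds": {k: list(v) for k, v in config.thresholds.items()},
        "inconclusive_policy": config.inconclusive_policy,
        "coefficient_versions": {k: v.version_label for k, v in registry.items()},
    }
    bundle = ReportBundle(accuracy_tables, roc_data, calibration_data, manifest, scores)
    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _pct(p: Optional[float]) -> Optional[float]:
    """Proportion -> percentage at the 1-decimal reporting precision (half-up)."""
    if p is None:
        return None
    return math.floor(p * 1000 + 0.5) / 10


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.accuracy_tables.items():
        df.to_csv(outdir / f"accuracy_{name}.csv")
    for model, df in bundle.roc_data.items():
        df.to_csv(outdir / f"roc_{model}.csv", index=False)
    for model, df in bundle.calibration_data.items():
        df.to_csv(outdir / f"calibration_{model}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


# --------------------------------------------------------------------------
# Replication of the published cohort-1 accuracy table from printed counts
# --------------------------------------------------------------------------


def _printed_counts_path():
    return resources.files("ovarisk.data").joinpath("printed_accuracy_cohort1.csv")


def _printed_pairwise_path():
    return resources.files("ovarisk.data").joinpath("printed_pairwise_cohort1.json")


def replicate_printed_table(
    counts_path=None, pairwise_path=None
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Recompute every derivable published accuracy cell from printed counts.

    For each test/threshold row of the shipped fixture (classification counts
    transcribed cell by cell from the published cohort-1 table) the 2x2
    metrics and exact CIs are recomputed and diffed against the printed values
    at 1-decimal precision.  The paired RMI-200-vs-250 comparison — the only
    pairwise row whose common-subset classification is fully determined by
    printed counts, because the thresholds are nested — is recomputed through
    the exact McNemar machinery.  Other pairwise rows are not derivable from
    printed marginals and are not checked.

    Returns (per-cell diff table, pairwise diff dict, list of mismatched cells).
    """
    if counts_path is None:
        with resources.as_file(_printed_counts_path()) as p:
            printed = pd.read_csv(p)
    else:
        printed = pd.read_csv(counts_path)
    mismatches: list[str] = []
    rows = []
    for _, row in printed.iterrows():
        tid = row["test_id"] if pd.isna(row["threshold"]) else f"{row['test_id']}@{row['threshold']:g}"
        table = TwoByTwo(
            tp=int(row["tp"]), fp=int(row["fp"]), fn=int(row["fn"]), tn=int(row["tn"]),
            n_missing_test=int(row["n_missing_case"] + row["n_missing_ctrl"]),
            n_inconclusive=int(row["n_inconclusive_case"] + row["n_inconclusive_ctrl"]),
            test_id=tid,
        )
        mets = accuracy_metrics(table)
        out = {"test_id": tid}
        for metric, short in (
            ("sensitivity", "sens"),
            ("specificity", "spec"),
            ("ppv", "ppv"),
            ("npv", "npv"),
        ):
            est = mets[metric]
            for part, value in (
                ("", est.point),
                ("_lo", est.ci_low),
                ("_hi", est.ci_high),
            ):
                col = f"{short}{part}"
                computed = _pct(value)
                expected = float(row[col])
                out[f"{col}_computed"] = computed
                out[f"{col}_printed"] = expected
                if computed != expected:
                    mismatches.append(f"{tid}.{col}: computed {computed} != printed {expected}")
        rows.append(out)
    diff = pd.DataFrame(rows).set_index("test_id")

    if pairwise_path is None:
        pairwise_printed = json.loads(_printed_pairwise_path().read_text())
    else:
        with open(pairwise_path) as fh:
            pairwise_printed = json.load(fh)
    pw = pairwise_printed["rmi1@200_vs_rmi1@250"]
    r200 = printed[(printed.test_id == "rmi1") & (printed.threshold == 200)].iloc[0]
    r250 = printed[(printed.test_id == "rmi1") & (printed.threshold == 250)].iloc[0]
    # nested thresholds: every 250-positive is 200-positive, so the paired
    # classification is fully determined by the marginal counts
    results_200, results_250, outcomes = {}, {}, {}
    k = 0

    def _add(n, state200, state250, outcome):
        nonlocal k
        for _ in range(int(n)):
            pid = f"x{k}"
            results_200[pid] = state200
            results_250[pid] = state250
            outcomes[pid] = outcome
            k += 1

    _add(r250["tp"], "positive", "positive", "positive")
    _add(r200["tp"] - r250["tp"], "positive", "negative", "positive")
    _add(r200["fn"], "negative", "negative", "positive")
    _add(r250["fp"], "positive", "positive", "negative")
    _add(r200["fp"] - r250["fp"], "positive", "negative", "negative")
    _add(r200["tn"], "negative", "negative", "negative")
    comp = mcnemar_paired(
        results_200, results_250, outcomes, test_a="rmi1@200", test_b="rmi1@250"
    )
    pairwise = {
        "n_common": {"computed": comp.n_common, "printed": pw["n_common"]},
        "delta_sensitivity": {
            "computed": _pct(comp.delta_sensitivity),
            "printed": pw["delta_sensitivity"],
        },
        "delta_sensitivity_ci": {
            "computed": [_pct(v) for v in comp.delta_sensitivity_ci],
            "printed": pw["delta_sensitivity_ci"],
        },
        "p_sensitivity": {"computed": round(comp.p_value_sens, 2), "printed": pw["p_sensitivity"]},
        "delta_specificity": {
            "computed": _pct(comp.delta_specificity),
            "printed": pw["delta_specificity"],
        },
        "delta_specificity_ci": {
            "computed": [_pct(v) for v in comp.delta_specificity_ci],
            "printed": pw["delta_specificity_ci"],
        },
        "p_specificity": {"computed": round(comp.p_value_spec, 2), "printed": pw["p_specificity"]},
    }
    for cell, v in pairwise.items():
        if v["computed"] != v["printed"]:
            mismatches.append(f"pairwise.{cell}: computed {v['computed']} != printed {v['printed']}")
    return diff, pairwise, mismatches
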
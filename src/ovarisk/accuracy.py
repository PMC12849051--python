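"""2x2 accuracy tables, exact binomial CIs, and paired McNemar comparisons.

Conventions follow a paired head-to-head diagnostic accuracy design:
participants whose outcome label is ``excluded`` are dropped first; missing
and inconclusive index-test results are then counted separately and excluded
from the four cells (the default policy — inconclusives are never counted as
positive, which would inflate sensitivity).  Sensitivity/specificity deltas
between two tests are computed on the participants conclusive on *both*
tests, within cases and within controls separately, with an exact McNemar
test on the discordant pairs and a Wald paired-difference CI (continuity
correction 1/n on by default, which reproduces published asymptotic
intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TwoByTwo",
    "AccuracyEstimate",
    "PairedComparison",
    "build_two_by_two",
    "proportion_with_ci",
    "accuracy_metrics",
    "mcnemar_paired",
    "mcnemar_exact_p",
    "adjust_multiplicity",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Conclusive-result contingency counts for one test at one threshold."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_missing_test: int = 0
    n_inconclusive: int = 0
    n_outcome_excluded: int = 0
    test_id: str = ""
    outcome_definition: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "n_missing_test", "n_inconclusive", "n_outcome_excluded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_conclusive(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class AccuracyEstimate:
    metric: str
    point: Optional[float]  # proportion, None when undefined (empty margin)
    ci_low: Optional[float]
    ci_high: Optional[float]
    numerator: int
    denominator: int
    ci_method: str = "clopper-pearson"

    @property
    def defined(self) -> bool:
        return self.point is not None


@dataclass(frozen=True)
class PairedComparison:
    test_a: str  # the test under evaluation
    test_b: str  # the comparator
    n_common: int
    n_cases: int
    n_controls: int
    delta_sensitivity: Optional[float]  # comparator minus test, proportion
    delta_sensitivity_ci: tuple[Optional[float], Optional[float]]
    p_value_sens: Optional[float]
    delta_specificity: Optional[float]
    delta_specificity_ci: tuple[Optional[float], Optional[float]]
    p_value_spec: Optional[float]
    significance_threshold: float = 0.05
    discordant: Mapping = field(default_factory=dict)


def build_two_by_two(
    results: Mapping[str, str],
    outcomes: Mapping[str, str],
    policy: str = "exclude",
    test_id: str = "",
    outcome_definition: str = "",
) -> TwoByTwo:
    """Cross-classify per-participant binary test results against outcome labels.

    ``results`` maps participant id to positive/negative/inconclusive/missing;
    ``outcomes`` maps id to positive/negative/excluded.  Both must be keyed by
    the same ids.  ``policy`` governs inconclusive results: ``exclude``
    (default), ``positive`` or ``negative`` (sensitivity analyses only).
    """
    if set(results) != set(outcomes):
        missing = set(results) ^ set(outcomes)
        raise ValueError(f"results/outcomes id mismatch, e.g. {sorted(missing)[:5]}")
    if policy not in ("exclude", "positive", "negative"):
        raise ValueError(f"unknown inconclusive policy {policy!r}")
    tp = fp = fn = tn = n_missing = n_inconclusive = n_excluded = 0
    for pid, outcome in outcomes.items():
        if outcome == "excluded":
            n_excluded += 1
            continue
        state = results[pid]
        if state == "missing":
            n_missing += 1
            continue
        if state == "inconclusive":
            if policy == "exclude":
                n_inconclusive += 1
                continue
            state = policy
        if state == "positive":
            if outcome == "positive":
                tp += 1
            else:
                fp += 1
        elif state == "negative":
            if outcome == "positive":
                fn += 1
            else:
                tn += 1
        else:
            raise ValueError(f"unknown test state {state!r} for participant {pid}")
    return TwoByTwo(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        n_missing_test=n_missing,
        n_inconclusive=n_inconclusive,
        n_outcome_excluded=n_excluded,
        test_id=test_id,
        outcome_definition=outcome_definition,
    )


def proportion_with_ci(
    numerator: int,
    denominator: int,
    method: str = "clopper-pearson",
    level: float = 0.95,
    metric: str = "proportion",
) -> AccuracyEstimate:
    """Binomial proportion with an exact Clopper-Pearson CI (default).

    A zero denominator yields an undefined estimate (point and CI ``None``)
    rather than an exception, so degenerate tables propagate as markers.
    """
    if denominator == 0:
        return AccuracyEstimate(metric, None, None, None, numerator, 0, method)
    if not 0 <= numerator <= denominator:
        raise ValueError(f"need 0 <= {numerator} <= {denominator}")
    alpha = 1.0 - level
    k, n = numerator, denominator
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return AccuracyEstimate(metric, k / n, lo, hi, k, n, method)


def accuracy_metrics(
    table: TwoByTwo, level: float = 0.95, ci_method: str = "clopper-pearson"
) -> dict[str, AccuracyEstimate]:
    """Sensitivity, specificity, PPV and NPV with CIs from one 2x2 table."""
    return {
        "sensitivity": proportion_with_ci(table.tp, table.tp + table.fn, ci_method, level, "sensitivity"),
        "specificity": proportion_with_ci(table.tn, table.tn + table.fp, ci_method, level, "specificity"),
        "ppv": proportion_with_ci(table.tp, table.tp + table.fp, ci_method, level, "ppv"),
        "npv": proportion_with_ci(table.tn, table.tn + table.fn, ci_method, level, "npv"),
    }


def mcnemar_exact_p(b: int, c: int) -> float:
    """Exact two-sided McNemar p from discordant counts: min(1, 2*P(X <= min(b,c)))
    with X ~ Binomial(b+c, 1/2); equals 1 when there is no discordance."""
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))


def _paired_delta(
    pos_a: Sequence[bool], pos_b: Sequence[bool], level: float, continuity: bool
) -> tuple[Optional[float], tuple[Optional[float], Optional[float]], Optional[float], dict]:
    """Delta (b-rate minus a-rate), Wald paired CI, exact McNemar p.

    ``b`` = positive on comparator only, ``c`` = positive on test a only.
    """
    n = len(pos_a)
    if n == 0:
        return None, (None, None), None, {}
    a = np.asarray(pos_a, dtype=bool)
    bmask = np.asarray(pos_b, dtype=bool)
    b = int((~a & bmask).sum())  # comparator-only positives
    c = int((a & ~bmask).sum())  # test-only positives
    delta = (b - c) / n
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(max(b + c - (b - c) ** 2 / n, 0.0)) / n
    half = z * se + (1.0 / n if continuity else 0.0)
    p = mcnemar_exact_p(b, c)
    return delta, (delta - half, delta + half), p, {"b": b, "c": c, "n": n}


def mcnemar_paired(
    test_a_results: Mapping[str, str],
    test_b_results: Mapping[str, str],
    outcomes: Mapping[str, str],
    level: float = 0.95,
    continuity_correction: bool = True,
    significance_threshold: float = 0.05,
    test_a: str = "test_a",
    test_b: str = "comparator",
) -> PairedComparison:
    """Paired sensitivity and specificity comparison of two tests.

    Restricted to participants with a conclusive result on both tests and a
    non-excluded outcome.  Deltas are comparator minus test (``test_b`` minus
    ``test_a``); the exact McNemar test is run on the discordant pairs within
    cases (sensitivity) and within controls (specificity) separately.
    """
    common = [
        pid
        for pid in outcomes
        if outcomes[pid] in ("positive", "negative")
        and test_a_results.get(pid) in ("positive", "negative")
        and test_b_results.get(pid) in ("positive", "negative")
    ]
    if not common:
        raise ValueError("no common participants with conclusive results on both tests")
    cases = [pid for pid in common if outcomes[pid] == "positive"]
    controls = [pid for pid in common if outcomes[pid] == "negative"]

    d_sens, ci_sens, p_sens, disc_sens = _paired_delta(
        [test_a_results[p] == "positive" for p in cases],
        [test_b_results[p] == "positive" for p in cases],
        level,
        continuity_correction,
    )
    # specificity deltas compare negative rates among controls
    d_spec, ci_spec, p_spec, disc_spec = _paired_delta(
        [test_a_results[p] == "negative" for p in controls],
        [test_b_results[p] == "negative" for p in controls],
        level,
        continuity_correction,
    )
    return PairedComparison(
        test_a=test_a,
        test_b=test_b,
        n_common=len(common),
        n_cases=len(cases),
        n_controls=len(controls),
        delta_sensitivity=d_sens,
        delta_sensitivity_ci=ci_sens,
        p_value_sens=p_sens,
        delta_specificity=d_spec,
        delta_specificity_ci=ci_spec,
        p_value_spec=p_spec,
        significance_threshold=significance_threshold,
        discordant={"sensitivity": disc_sens, "specificity": disc_spec},
    )


def adjust_multiplicity(
    p_values: Sequence[Optional[float]], n_comparisons: int
) -> tuple[list[Optional[bool]], float]:
    """Bonferroni significance flags.

    The adjusted alpha is 0.005 for the 11-comparison family (the rounded
    convention of the source analysis) and 0.05/n otherwise; flags are
    ``p < alpha`` (None p-values stay None).
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    alpha = 0.005 if n_comparisons == 11 else 0.05 / n_comparisons
    flags = [None if p is None else bool(p < alpha) for p in p_values]
    return flags, alpha
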
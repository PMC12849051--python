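"""2x2 construction, exact CIs, McNemar comparisons, multiplicity."""

import numpy as np
import pytest
from scipy.special import comb

from ovarisk import (
    TwoByTwo,
    accuracy_metrics,
    adjust_multiplicity,
    build_two_by_two,
    mcnemar_paired,
    proportion_with_ci,
)
from ovarisk.accuracy import mcnemar_exact_p


def _cohort_results(tp, fp, fn, tn, miss_case=0, miss_ctrl=0, inc_case=0, inc_ctrl=0, excluded=0):
    results, outcomes = {}, {}
    k = 0

    def add(n, state, outcome):
        nonlocal k
        for _ in range(n):
            results[f"p{k}"] = state
            outcomes[f"p{k}"] = outcome
            k += 1

    add(tp, "positive", "positive")
    add(fn, "negative", "positive")
    add(miss_case, "missing", "positive")
    add(inc_case, "inconclusive", "positive")
    add(fp, "positive", "negative")
    add(tn, "negative", "negative")
    add(miss_ctrl, "missing", "negative")
    add(inc_ctrl, "inconclusive", "negative")
    add(excluded, "positive", "excluded")
    return results, outcomes


def test_build_two_by_two_published_cohort_layout():
    """RMI-at-250 layout: 49 cancers (2 missing), 750 non-cancers (125 missing)."""
    results, outcomes = _cohort_results(20, 22, 27, 603, miss_case=2, miss_ctrl=125)
    t = build_two_by_two(results, outcomes, test_id="rmi1@250")
    assert (t.tp, t.fp, t.fn, t.tn) == (20, 22, 27, 603)
    assert t.n_missing_test == 127
    assert t.n_conclusive + t.n_missing_test + t.n_inconclusive == 799


def test_build_two_by_two_inconclusive_removed_before_cells():
    """Simple-rules layout: 15 cancer + 105 non-cancer inconclusives set aside."""
    results, outcomes = _cohort_results(
        24, 25, 8, 496, miss_case=2, miss_ctrl=124, inc_case=15, inc_ctrl=105
    )
    t = build_two_by_two(results, outcomes, test_id="simple_rules")
    assert (t.tp, t.fp, t.fn, t.tn) == (24, 25, 8, 496)
    assert t.n_inconclusive == 120
    # alternative policies reassign rather than drop
    t_pos = build_two_by_two(results, outcomes, policy="positive")
    assert (t_pos.tp, t_pos.fp) == (24 + 15, 25 + 105)


def test_build_two_by_two_degenerate_and_errors():
    results, outcomes = _cohort_results(5, 0, 0, 0)
    t = build_two_by_two(results, outcomes)
    assert (t.tp, t.fp, t.fn, t.tn) == (5, 0, 0, 0)
    with pytest.raises(ValueError, match="mismatch"):
        build_two_by_two({"a": "positive"}, {"b": "positive"})
    with pytest.raises(ValueError):
        TwoByTwo(tp=-1, fp=0, fn=0, tn=0)


@pytest.mark.parametrize(
    "k,n,point,lo,hi",
    [
        (20, 47, 42.6, 28.3, 57.8),
        (27, 49, 55.1, 40.2, 69.3),
        (603, 625, 96.5, 94.7, 97.8),
    ],
)
def test_clopper_pearson_reproduces_published_intervals(k, n, point, lo, hi):
    est = proportion_with_ci(k, n)
    assert round(100 * est.point, 1) == point
    assert round(100 * est.ci_low, 1) == lo
    assert round(100 * est.ci_high, 1) == hi


def test_proportion_boundary_and_undefined():
    est = proportion_with_ci(0, 10)
    assert est.point == 0.0 and est.ci_low == 0.0 and est.ci_high > 0
    est = proportion_with_ci(10, 10)
    assert est.ci_high == 1.0
    und = proportion_with_ci(0, 0)
    assert not und.defined and und.point is None
    wilson = proportion_with_ci(20, 47, method="wilson")
    assert wilson.ci_low < 20 / 47 < wilson.ci_high


def test_accuracy_metrics_published_cells():
    t = TwoByTwo(tp=20, fp=22, fn=27, tn=603)
    m = accuracy_metrics(t)
    assert round(100 * m["ppv"].point, 1) == 47.6
    assert round(100 * m["npv"].point, 1) == 95.7
    assert round(100 * m["npv"].ci_low, 1) == 93.8 and round(100 * m["npv"].ci_high, 1) == 97.2


def test_accuracy_metrics_label_swap_symmetry():
    """Swapping outcome labels swaps sens<->spec and ppv<->npv exactly."""
    t = TwoByTwo(tp=13, fp=7, fn=4, tn=50)
    swapped = TwoByTwo(tp=50, fp=4, fn=7, tn=13)
    m, s = accuracy_metrics(t), accuracy_metrics(swapped)
    assert m["sensitivity"].point == s["specificity"].point
    assert m["ppv"].point == s["npv"].point
    assert m["sensitivity"].ci_low == s["specificity"].ci_low


def test_accuracy_metrics_empty_margin_marker():
    t = TwoByTwo(tp=0, fp=0, fn=0, tn=10)
    m = accuracy_metrics(t)
    assert not m["sensitivity"].defined and not m["ppv"].defined
    assert m["specificity"].defined


# ------------------------------------------------------------------ McNemar


def test_mcnemar_exact_p_frozen_values():
    # independent oracle: 2 * sum_{k<=min(b,c)} C(n,k) / 2^n
    assert mcnemar_exact_p(0, 0) == 1.0
    assert mcnemar_exact_p(5, 1) == pytest.approx(2 * (comb(6, 0) + comb(6, 1)) / 2**6)  # 0.21875
    assert mcnemar_exact_p(3, 0) == pytest.approx(0.25)
    assert mcnemar_exact_p(7, 0) == pytest.approx(2 / 128)


def test_mcnemar_symmetry_and_statsmodels_cross_check():
    rng = np.random.default_rng(5)
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    for _ in range(25):
        b, c = rng.integers(0, 15, size=2)
        assert mcnemar_exact_p(b, c) == mcnemar_exact_p(c, b)
        if b + c > 0:
            ref = sm_mcnemar([[1, b], [c, 1]], exact=True).pvalue
            assert mcnemar_exact_p(b, c) == pytest.approx(ref)


def test_mcnemar_paired_nested_thresholds():
    """RMI 200 vs 250 on the common n=672: delta sens -6.4 points, p=0.25."""
    results_a, results_b, outcomes = {}, {}, {}
    k = 0

    def add(n, a, b, y):
        nonlocal k
        for _ in range(n):
            results_a[f"p{k}"], results_b[f"p{k}"], outcomes[f"p{k}"] = a, b, y
            k += 1

    add(20, "positive", "positive", "positive")
    add(3, "positive", "negative", "positive")
    add(24, "negative", "negative", "positive")
    add(22, "positive", "positive", "negative")
    add(7, "positive", "negative", "negative")
    add(596, "negative", "negative", "negative")
    comp = mcnemar_paired(results_a, results_b, outcomes, test_a="rmi1@200", test_b="rmi1@250")
    assert comp.n_common == 672
    assert round(100 * comp.delta_sensitivity, 1) == -6.4
    assert comp.p_value_sens == pytest.approx(0.25)
    assert round(100 * comp.delta_sensitivity_ci[0], 1) == -15.5
    assert round(100 * comp.delta_sensitivity_ci[1], 1) == 2.7
    assert round(100 * comp.delta_specificity, 1) == 1.1
    assert comp.p_value_spec == pytest.approx(2 / 128)


def test_mcnemar_paired_no_discordance_and_no_common():
    results, outcomes = _cohort_results(5, 2, 3, 10)
    comp = mcnemar_paired(results, results, outcomes)
    assert comp.p_value_sens == 1.0 and comp.p_value_spec == 1.0
    assert comp.delta_sensitivity == 0.0
    assert comp.delta_sensitivity_ci == (0.0, 0.0) or comp.delta_sensitivity_ci[0] <= 0 <= comp.delta_sensitivity_ci[1]
    with pytest.raises(ValueError):
        mcnemar_paired({"a": "missing"}, {"a": "positive"}, {"a": "positive"})


def test_mcnemar_restricts_to_conclusive_in_both():
    results_a, outcomes = _cohort_results(10, 5, 5, 30)
    results_b = dict(results_a)
    # knock three participants out of test b only
    for pid in list(results_b)[:3]:
        results_b[pid] = "missing"
    comp = mcnemar_paired(results_a, results_b, outcomes)
    assert comp.n_common == 50 - 3


# ------------------------------------------------------------- multiplicity


def test_bonferroni_adjustment():
    flags, alpha = adjust_multiplicity([0.004, 0.006, None], 11)
    assert alpha == 0.005  # the 11-comparison family uses the rounded alpha
    assert flags == [True, False, None]
    _, alpha1 = adjust_multiplicity([0.04], 1)
    assert alpha1 == 0.05
    _, alpha4 = adjust_multiplicity([0.01], 4)
    assert alpha4 == pytest.approx(0.0125)
    with pytest.raises(ValueError):
        adjust_multiplicity([0.1], 0)


def test_clopper_pearson_exact_coverage():
    """CP coverage >= nominal, computed exactly by summing binomial pmf over
    the acceptance region (no simulation) on a reduced (n, p) grid."""
    from scipy import stats

    for n in (10, 25, 60):
        for p in (0.05, 0.3, 0.5, 0.8):
            cover = 0.0
            for k in range(n + 1):
                est = proportion_with_ci(k, n)
                if est.ci_low <= p <= est.ci_high:
                    cover += stats.binom.pmf(k, n, p)
            assert cover >= 0.95 - 1e-12
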
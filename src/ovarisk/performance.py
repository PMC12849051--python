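"""Discrimination and calibration of continuous risk scores.

Discrimination: the C-index (probability a random case outranks a random
control, ties counted one half — identical to the area under the ROC curve
for a binary outcome), with a DeLong asymptotic CI.  Calibration: a decile
table of mean predicted vs observed risk, the calibration slope (coefficient
of a logistic regression of the outcome on the logit of predicted risk;
ideal 1), and calibration-in-the-large (intercept of the same regression with
the slope fixed at 1 via an offset; ideal 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "CIndexResult",
    "RocCurve",
    "CalibrationReport",
    "SlopeResult",
    "c_index",
    "roc_points",
    "calibration_deciles",
    "calibration_slope",
    "calibration_in_the_large",
]


@dataclass(frozen=True)
class CIndexResult:
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_cases: int
    n_controls: int
    se: Optional[float] = None
    ci_method: str = "delong"

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class CalibrationReport:
    groups: pd.DataFrame  # columns: n, mean_predicted, observed
    n_groups: int
    fallback_quintiles: bool = False


@dataclass(frozen=True)
class SlopeResult:
    slope: Optional[float]
    intercept: Optional[float]
    slope_ci: tuple[Optional[float], Optional[float]]
    converged: bool
    flag: str = ""


def _clean(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    keep = ~np.isnan(s) & ~np.isnan(y)
    return s[keep], y[keep].astype(int)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def c_index(scores, outcomes, ci_method: str = "delong", level: float = 0.95) -> CIndexResult:
    """C-index with DeLong variance.

    Single-class input (no cases or no controls after dropping missing
    scores) yields an undefined-estimate marker rather than an exception.
    """
    s, y = _clean(scores, outcomes)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        return CIndexResult(None, None, None, m, n)
    # midrank formulation of the Mann-Whitney statistic and DeLong components
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # structural components, cases
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # controls
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return CIndexResult(float(auc), float(lo), float(hi), m, n, se=se)


def roc_points(scores, outcomes) -> RocCurve:
    """ROC staircase: one point per distinct score plus the (0,0)/(1,1)
    endpoints; the trapezoidal area equals the pair-counting C-index."""
    from sklearn.metrics import roc_curve as _sk_roc

    s, y = _clean(scores, outcomes)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_points needs both outcome classes")
    fpr, tpr, thr = _sk_roc(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def calibration_deciles(risks, outcomes, n_groups: int = 10) -> CalibrationReport:
    """Group participants into near-equal deciles of predicted risk.

    Participants with identical risks always land in the same group (tied
    quantile edges are merged), so the effective number of groups can be
    smaller than requested.  With fewer than 10 participants the grouping
    falls back to quintiles with a warning.
    """
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must be probabilities in [0, 1]")
    fallback = False
    if len(r) < 10 and n_groups > 5:
        warnings.warn("fewer than 10 participants: falling back to quintiles", stacklevel=2)
        n_groups, fallback = 5, True
    df = pd.DataFrame({"risk": r, "y": y})
    try:
        df["group"] = pd.qcut(df["risk"].rank(method="first"), q=n_groups, labels=False)
    except ValueError:  # fewer distinct ranks than groups
        df["group"] = 0
    # keep ties together: participants sharing a risk take the lowest group seen
    df["group"] = df.groupby("risk")["group"].transform("min")
    grouped = (
        df.groupby("group")
        .agg(n=("y", "size"), mean_predicted=("risk", "mean"), observed=("y", "mean"))
        .reset_index(drop=True)
    )
    return CalibrationReport(groups=grouped, n_groups=len(grouped), fallback_quintiles=fallback)


_EPS = 1e-6


def calibration_slope(risks, outcomes, eps: float = _EPS, level: float = 0.95) -> SlopeResult:
    """Logistic recalibration: outcome ~ intercept + slope * logit(risk).

    Risks are clipped to [eps, 1-eps] before the logit.  Constant risks or a
    non-converged fit return a flagged estimate instead of raising.
    """
    import statsmodels.api as sm

    r = np.clip(np.asarray(risks, dtype=float), eps, 1 - eps)
    y = np.asarray(outcomes, dtype=float)
    lp = logit(r)
    if np.allclose(lp, lp[0]):
        return SlopeResult(None, None, (None, None), False, flag="constant risks")
    X = sm.add_constant(lp)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        ci = fit.conf_int(alpha=1 - level)
        return SlopeResult(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            slope_ci=(float(ci[1][0]), float(ci[1][1])),
            converged=converged,
            flag="" if converged else "non-convergence",
        )
    except Exception as exc:  # perfect separation etc.
        return SlopeResult(None, None, (None, None), False, flag=str(exc))


def calibration_in_the_large(risks, outcomes, eps: float = _EPS) -> Optional[float]:
    """Intercept of outcome ~ offset(logit(risk)); 0 means the mean predicted
    risk matches the observed event rate on the logit scale."""
    import statsmodels.api as sm

    r = np.clip(np.asarray(risks, dtype=float), eps, 1 - eps)
    y = np.asarray(outcomes, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=logit(r)
            ).fit()
        return float(fit.params[0])
    except Exception:
        return None
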
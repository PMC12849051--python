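"""Multiple imputation by chained equations and Rubin-rules pooling.

Imputation targets the *predictors* of the index tests (markers, ultrasound
variables), never the derived scores: each completed dataset re-scores the
models from its imputed predictors.  The chained-equations engine is
statsmodels' MICE machinery (predictive mean matching conditionals); this
module wraps it with a reproducible seeding contract and guards.

Accuracy proportions from the completed datasets are pooled on the logit
scale with Rubin's rules: pooled variance = within + (1 + 1/m) * between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .accuracy import AccuracyEstimate

__all__ = ["ImputationSpec", "PooledEstimate", "ImputationError", "mice_impute", "pool_accuracy"]


class ImputationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImputationSpec:
    """Settings for chained-equations imputation.

    ``m`` completed datasets, ``iterations`` burn-in cycles each, predictive
    mean matching with ``k_pmm`` donors for continuous conditionals.  Binary
    0/1 variables are also handled by PMM (donors are observed values, so
    imputations stay in {0, 1}).  ``variable_models`` can override the
    conditional per variable ("pmm" is currently the only engine exposed).
    """

    m: int = 10
    iterations: int = 10
    k_pmm: int = 5
    seed: int = 0
    variable_models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 imputations")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


def mice_impute(df: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of a numeric DataFrame.

    Observed cells are never altered.  A cohort with no missing values comes
    back as ``m`` identical copies.  Reproducible for a fixed ``spec.seed``.

    Raises
    ------
    ImputationError
        If any column is entirely missing (no observed donors).
    """
    from statsmodels.imputation.mice import MICEData

    num = df.apply(pd.to_numeric, errors="raise")
    all_missing = [c for c in num.columns if num[c].isna().all()]
    if all_missing:
        raise ImputationError(f"variables entirely missing: {all_missing}")
    if not num.isna().any().any():
        return [num.copy() for _ in range(spec.m)]

    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.m) % (2**31 - 1)
    completed = []
    for i in range(spec.m):
        np.random.seed(int(seeds[i]))  # MICEData draws from the global stream
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imp = MICEData(num, k_pmm=spec.k_pmm)
            for _ in range(spec.iterations):
                imp.update_all()
        out = imp.data.copy()
        out.index = num.index
        # contract: observed values untouched
        observed = ~num.isna()
        assert (out[observed] == num[observed]).all().all() or np.allclose(
            out.values[observed.values], num.values[observed.values], equal_nan=True
        )
        completed.append(out)
    return completed


@dataclass(frozen=True)
class PooledEstimate:
    metric: str
    pooled_point: float
    pooled_ci: tuple[float, float]
    within_var: float
    between_var: float
    m_used: int
    flag: str = ""

    @property
    def total_var(self) -> float:
        return self.within_var + (1 + 1 / self.m_used) * self.between_var


def _logit_and_var(est: AccuracyEstimate) -> tuple[float, float, bool]:
    """Delta-method logit transform of k/n; 0.5 continuity adjustment at the
    boundary (flagged)."""
    k, n = est.numerator, est.denominator
    adjusted = False
    if k == 0 or k == n:
        k, n, adjusted = k + 0.5, n + 1.0, True
    theta = logit(k / n)
    var = 1.0 / k + 1.0 / (n - k)
    return float(theta), float(var), adjusted


def pool_accuracy(estimates: Sequence[AccuracyEstimate], level: float = 0.95) -> PooledEstimate:
    """Rubin's rules on the logit scale across per-imputation estimates.

    The pooled CI uses the Barnard-Rubin small-sample degrees of freedom and
    is back-transformed to the proportion scale.
    """
    if len(estimates) < 2:
        raise ValueError("pooling needs at least two per-imputation estimates")
    metric = estimates[0].metric
    if any(e.metric != metric for e in estimates):
        raise ValueError("all estimates must be of the same metric")
    thetas, variances, flags = [], [], []
    for e in estimates:
        t, v, adj = _logit_and_var(e)
        thetas.append(t)
        variances.append(v)
        flags.append(adj)
    m = len(thetas)
    qbar = float(np.mean(thetas))
    w = float(np.mean(variances))
    b = float(np.var(thetas, ddof=1))
    t_var = w + (1 + 1 / m) * b
    if b > 0:
        r = (1 + 1 / m) * b / w
        df = (m - 1) * (1 + 1 / r) ** 2
    else:
        df = np.inf
    tcrit = stats.t.ppf(0.5 + level / 2, df) if np.isfinite(df) else stats.norm.ppf(0.5 + level / 2)
    half = float(tcrit) * np.sqrt(t_var)
    return PooledEstimate(
        metric=metric,
        pooled_point=float(expit(qbar)),
        pooled_ci=(float(expit(qbar - half)), float(expit(qbar + half))),
        within_var=w,
        between_var=b,
        m_used=m,
        flag="continuity-adjusted" if any(flags) else "",
    )
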
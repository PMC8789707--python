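"""Validity statistics: FAB-MoCA correlation battery with Bonferroni
control, sub-scale intercorrelations, sex-difference tests, and the
noncentral-F power analysis for the minimum norming sample size."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort
from .errors import ConfigError, DegenerateDataError

FAB_MEASURES = ("FAB", "FAB1", "FAB2", "FAB3")
MOCA_MEASURES = ("moca_total", "moca_ef", "moca_a", "moca_l", "moca_m",
                 "moca_vs", "moca_o")


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    method: str
    coefficient: float
    n: int
    p_value: float
    alpha_adjusted: float
    significant: bool
    undefined: bool = False


def _measure_frame(cohort: Cohort, names: Sequence[str]) -> pd.DataFrame:
    scores = cohort.scores()
    cols = {}
    for name in names:
        if name in scores.columns:
            cols[name] = scores[name].astype(float)
        else:
            cols[name] = pd.to_numeric(cohort.df[name], errors="coerce")
    return pd.DataFrame(cols)


def _correlate(x: pd.Series, y: pd.Series, method: str,
               alpha_adjusted: float) -> CorrelationResult:
    ok = x.notna() & y.notna()  # pairwise-complete observations
    xv, yv = x[ok].to_numpy(float), y[ok].to_numpy(float)
    n = int(ok.sum())
    if n < 3 or np.std(xv) == 0.0 or np.std(yv) == 0.0:
        return CorrelationResult(str(x.name), str(y.name), method,
                                 float("nan"), n, float("nan"),
                                 alpha_adjusted, False, undefined=True)
    if method == "spearman":
        r, p = stats.spearmanr(xv, yv)  # average ranks for ties
    elif method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    else:
        raise ConfigError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return CorrelationResult(str(x.name), str(y.name), method, float(r), n,
                             float(p), alpha_adjusted, bool(p < alpha_adjusted))


def correlation_battery(cohort: Cohort,
                        fab_measures: Sequence[str] = FAB_MEASURES,
                        moca_measures: Sequence[str] = MOCA_MEASURES,
                        method: str = "spearman",
                        family_alpha: float = 0.05) -> list[CorrelationResult]:
    """All FAB x MoCA correlations under Bonferroni family control.

    With the default 4 x 7 battery, k = 28 and the adjusted alpha is
    0.05/28 (0.0017 at 4-decimal precision).
    """
    pairs = [(f, m) for f in fab_measures for m in moca_measures]
    k = len(pairs)
    if k == 0:
        raise ConfigError("empty battery")
    alpha_adjusted = family_alpha / k
    frame = _measure_frame(cohort, list(dict.fromkeys(
        list(fab_measures) + list(moca_measures))))
    return [_correlate(frame[f], frame[m], method, alpha_adjusted)
            for f, m in pairs]


def subscale_battery(cohort: Cohort, method: str = "spearman",
                     family_alpha: float = 0.05) -> list[CorrelationResult]:
    """The three sub-scale pairwise correlations plus each sub-scale
    against the FAB total (part-whole)."""
    frame = _measure_frame(cohort, FAB_MEASURES)
    pairs = [("FAB1", "FAB2"), ("FAB1", "FAB3"), ("FAB2", "FAB3"),
             ("FAB1", "FAB"), ("FAB2", "FAB"), ("FAB3", "FAB")]
    alpha_adjusted = family_alpha / len(pairs)
    return [_correlate(frame[a], frame[b], method, alpha_adjusted)
            for a, b in pairs]


def battery_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass(frozen=True)
class SexTestResult:
    scale: str
    t: float
    df: float
    p_value: float
    mean_f: float
    mean_m: float
    pooled: bool  # False = unequal-variance (Welch) test
    variance_p: float


def sex_tests(cohort: Cohort, scales: Sequence[str] = FAB_MEASURES,
              variance_policy: str = "pretest",
              pretest_alpha: float = 0.05) -> list[SexTestResult]:
    """Two-sample t-test of F vs M per scale.

    ``variance_policy``: ``"pretest"`` (default) runs a two-sided F-ratio
    variance-homogeneity test per scale and switches to the Welch
    unequal-variance test (fractional df) when it rejects; ``"pooled"``
    and ``"welch"`` force one test.
    """
    if variance_policy not in ("pretest", "pooled", "welch"):
        raise ConfigError(f"unknown variance_policy {variance_policy!r}")
    sex = cohort.df["sex"]
    if not {"F", "M"} <= set(sex.unique()):
        raise DegenerateDataError("both sexes must be represented")
    frame = _measure_frame(cohort, scales)
    out = []
    for name in scales:
        xf = frame.loc[sex == "F", name].dropna().to_numpy(float)
        xm = frame.loc[sex == "M", name].dropna().to_numpy(float)
        if len(xf) < 2 or len(xm) < 2:
            raise DegenerateDataError(f"{name}: need n >= 2 per sex")
        vf, vm = np.var(xf, ddof=1), np.var(xm, ddof=1)
        if vm > 0 and vf > 0:
            fstat = vf / vm
            cdf = stats.f.cdf(fstat, len(xf) - 1, len(xm) - 1)
            var_p = float(2 * min(cdf, 1 - cdf))
        else:
            var_p = 0.0
        if variance_policy == "pooled":
            pooled = True
        elif variance_policy == "welch":
            pooled = False
        else:
            pooled = var_p >= pretest_alpha
        res = stats.ttest_ind(xf, xm, equal_var=pooled)
        df = (len(xf) + len(xm) - 2) if pooled else float(res.df)
        out.append(SexTestResult(name, float(res.statistic), float(df),
                                 float(res.pvalue), float(np.mean(xf)),
                                 float(np.mean(xm)), pooled, var_p))
    return out


# ---------------------------------------------------------------------------
# Power analysis for multiple linear regression (Cohen's f^2 convention)

def regression_power(n: float, u: int, f2: float, alpha: float) -> float:
    """Power of the F-test of u regression terms at sample size n.

    Denominator df v = n - u - 1; noncentrality lambda = f2 * (u + v + 1)
    = f2 * n.
    """
    v = n - u - 1
    if v <= 0:
        return 0.0
    lam = f2 * (u + v + 1)
    fcrit = stats.f.isf(alpha, u, v)
    return float(stats.ncf.sf(fcrit, u, v, lam))


def min_sample_size(u: int = 3, f2: float = 0.05, alpha: float = 0.05,
                    power: float = 0.9, rounding: str = "nearest") -> int:
    """Minimum sample size for the regression F-test to reach ``power``.

    The power equation is solved continuously in n (the convention of
    the standard power-analysis tools, which treat the denominator df as
    real-valued); ``rounding="nearest"`` (default) reports the nearest
    whole participant, ``rounding="ceil"`` the smallest integer n whose
    power actually meets the target (one more when the continuous
    solution is fractional, as it almost always is).
    """
    if f2 <= 0:
        raise ConfigError("f2 must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigError("alpha and power must lie in (0, 1)")
    if rounding not in ("nearest", "ceil"):
        raise ConfigError(f"rounding must be 'nearest' or 'ceil', got {rounding!r}")
    lo = u + 2.0
    if regression_power(lo, u, f2, alpha) >= power:
        return int(lo)
    hi = lo + 8.0
    while regression_power(hi, u, f2, alpha) < power:
        hi *= 2.0
        if hi > 1e8:
            raise ConfigError("target power unreachable")
    n_star = optimize.brentq(
        lambda n: regression_power(n, u, f2, alpha) - power, lo, hi, xtol=1e-9)
    if rounding == "nearest":
        n_min = int(round(n_star))
    else:
        n_min = int(math.ceil(n_star - 1e-9))
        if regression_power(n_min, u, f2, alpha) < power:
            n_min += 1
    return max(n_min, u + 2)
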
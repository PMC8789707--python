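"""Non-parametric tolerance limits and Equivalent Score construction.

The equivalent-score (ES) method classifies a demographically adjusted
score (AS) on an ordinal 0-4 scale anchored to distribution-free
tolerance limits on the population 5th centile:

* the *outer* tolerance limit (oTL) is the largest order statistic that
  is a lower 95%-confidence bound on the 5th centile — an AS at or below
  it is confidently abnormal (ES = 0);
* the *inner* tolerance limit (iTL) is the smallest order statistic that
  is an upper 95%-confidence bound on the 5th centile; scores between
  the two limits are of uncertain classification;
* ES = 4 is anything above the sample median; ES 1-3 partition the
  interval (oTL, median].

Both limits come from the binomial distribution of the number of
observations below the population centile: the r-th smallest of n
observations lies below the q-th population centile with probability
P(Binomial(n, q) >= r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateDataError, NormsUnderivableError
from .adjustment import round_half_up

ES_LABELS = {0: "abnormal", 1: "borderline", 2: "low-end normal",
             3: "normal", 4: "normal"}


@dataclass(frozen=True)
class ESLevel:
    level: int
    label: str

    def __post_init__(self) -> None:
        if self.level not in ES_LABELS:
            raise ConfigError(f"ES level must be 0..4, got {self.level}")


@dataclass(frozen=True)
class ToleranceRanks:
    """1-based ranks of the outer and inner tolerance limits.

    ``outer`` is None when no order statistic is a valid lower confidence
    bound (small n).
    """

    outer: int | None
    inner: int


def tolerance_ranks(n: int, centile: float = 0.05,
                    confidence: float = 0.95) -> ToleranceRanks:
    """Order-statistic ranks of the outer and inner tolerance limits.

    outer r: largest r with P(Binomial(n, centile) >= r) >= confidence,
    inner s: smallest s with P(Binomial(n, centile) >= s) <= 1 - confidence.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if not (0.0 < centile < 1.0) or not (0.0 < confidence < 1.0):
        raise ConfigError("centile and confidence must lie in (0, 1)")
    ks = np.arange(1, n + 2)
    # tail[k-1] = P(X >= k) = sf(k-1); decreasing in k; P(X >= n+1) = 0
    tail = stats.binom.sf(ks - 1, n, centile)
    outer_ok = tail >= confidence
    outer = int(ks[outer_ok][-1]) if outer_ok.any() else None
    inner_ok = tail <= 1.0 - confidence
    inner = int(ks[inner_ok][0])
    inner = min(inner, n)  # an upper bound beyond the sample maximum degenerates to it
    return ToleranceRanks(outer, inner)


@dataclass(frozen=True)
class NormTable:
    """ES classification thresholds for one scale (a norms-table row).

    Thresholds are on the adjusted-score metric: ES 0 is AS <= oTL,
    ES 1-3 are (oTL, t1], (t1, t2], (t2, median], ES 4 is AS > median.
    All intervals are closed on the right.
    """

    scale: str
    n: int
    oTL: float
    iTL: float
    median: float
    t1: float
    t2: float
    scheme: str
    precision: int = 2
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not (self.oTL <= self.t1 <= self.t2 <= self.median):
                raise ConfigError(
                    f"{self.scale}: thresholds must satisfy oTL <= t1 <= t2 "
                    f"<= median, got {self.oTL}, {self.t1}, {self.t2}, {self.median}")
            if self.oTL > self.iTL:
                raise ConfigError(f"{self.scale}: oTL {self.oTL} > iTL {self.iTL}")

    def to_dict(self) -> dict:
        return {"scale": self.scale, "n": self.n, "oTL": self.oTL,
                "iTL": self.iTL, "median": self.median, "t1": self.t1,
                "t2": self.t2, "scheme": self.scheme,
                "precision": self.precision}


# ES 1-3 inner thresholds, z-interval scheme: the interval from the 5th
# centile's z (-1.6449) up to the median's z (0) is cut into equal
# thirds; the cuts map back to empirical centiles ~13.6% and ~29.2%.
_Z5 = stats.norm.ppf(0.05)
Z_SCHEME_CENTILES = (float(stats.norm.cdf(_Z5 * 2 / 3)),
                     float(stats.norm.cdf(_Z5 / 3)))


def _order_stat(sorted_values: np.ndarray, p: float) -> float:
    """Empirical quantile as the ceil(p*n)-th order statistic."""
    n = sorted_values.size
    k = min(max(int(np.ceil(p * n)), 1), n)
    return float(sorted_values[k - 1])


def compute_norm_table(adjusted_scores: Sequence[float], scale: str = "score",
                       scheme: str = "z-intervals", centile: float = 0.05,
                       confidence: float = 0.95,
                       precision: int = 2) -> NormTable:
    """Derive a norms-table row from a sample of adjusted scores.

    ``scheme`` picks the ES 1-3 inner thresholds: ``"z-intervals"``
    (default) places t1, t2 at the empirical centiles corresponding to
    equal thirds of the z-interval [z(centile), 0]; ``"equal-count"``
    spaces the thresholds' ranks evenly between the outer rank and the
    median rank.
    """
    x = np.sort(np.asarray(adjusted_scores, dtype=float))
    n = x.size
    if n < 2:
        raise DegenerateDataError(f"need n >= 2 adjusted scores, got {n}")
    ranks = tolerance_ranks(n, centile, confidence)
    if ranks.outer is None:
        raise NormsUnderivableError(
            f"no valid outer tolerance rank at n={n} (centile {centile}, "
            f"confidence {confidence}); norms are not derivable")
    oTL = float(x[ranks.outer - 1])
    iTL = float(x[ranks.inner - 1])
    median = float(np.median(x))
    if x[0] == x[-1]:
        v = round_half_up(float(x[0]), precision)
        return NormTable(scale, n, v, v, v, v, v, scheme, precision,
                         degenerate=True)
    if scheme == "z-intervals":
        p1, p2 = Z_SCHEME_CENTILES
        t1 = _order_stat(x, p1)
        t2 = _order_stat(x, p2)
    elif scheme == "equal-count":
        m_rank = int(np.ceil(n / 2))
        r = ranks.outer
        t1 = float(x[r - 1 + int(round((m_rank - r) / 3))])
        t2 = float(x[r - 1 + int(round(2 * (m_rank - r) / 3))])
    else:
        raise ConfigError(f"unknown scheme {scheme!r}")
    t1, t2 = max(t1, oTL), max(t2, oTL)
    t2 = min(t2, median)
    t1 = min(t1, t2)
    rh = lambda v: round_half_up(v, precision)
    return NormTable(scale, n, rh(oTL), rh(iTL), rh(median), rh(t1), rh(t2),
                     scheme, precision)


def classify_es(adjusted_score: float, table: NormTable) -> ESLevel:
    """Equivalent Score of one adjusted score under a norms table.

    Total over the reals: 0 if AS <= oTL, 4 if AS > median, else 1-3 by
    the right-closed inner intervals.
    """
    a = float(adjusted_score)
    if a <= table.oTL:
        level = 0
    elif a > table.median:
        level = 4
    elif a <= table.t1:
        level = 1
    elif a <= table.t2:
        level = 2
    else:
        level = 3
    return ESLevel(level, ES_LABELS[level])
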
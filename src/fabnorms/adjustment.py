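"""Demographic adjustment: predictor transforms, regression fitting,
transform selection and age x education correction grids.

The adjustment removes estimated age and education effects from a raw
score RS:

    AS = RS + c_age * (T_age(age) - m_age) + c_edu * (T_edu(edu) - m_edu)

where T are the selected transforms (e.g. cubic age, logarithmic
education), m their centering constants (sample means of the transformed
predictors) and c the adjustment coefficients, i.e. the *negated* fitted
regression slopes: a subject older or less educated than average receives
a positive correction.  Adjustment is affine in RS with unit slope, so
score differences are preserved exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .errors import ConfigError, SingularFitError, TransformDomainError
from .scales import ScaleDefinition

TRANSFORM_FAMILIES = {
    "identity": lambda x: x,
    "square": lambda x: x ** 2,
    "cube": lambda x: x ** 3,
    "log": np.log,
    "reciprocal": lambda x: np.asarray(1.0, dtype=float) / x,
}

#: Default candidate families per predictor for transform selection.
DEFAULT_AGE_CANDIDATES = ("identity", "square", "cube")
DEFAULT_EDU_CANDIDATES = ("identity", "log", "reciprocal")

#: Default display lattices for the correction grids.
DEFAULT_GRID_AGES = tuple(range(35, 100, 5))
DEFAULT_GRID_EDUCATIONS = (5, 8, 11, 13, 16, 18, 21)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero at ``decimals`` places (display
    convention of the printed grids; banker's rounding would disagree on
    exact .xx5 ties)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransformSpec:
    """One predictor's transform and centering constant."""

    predictor: str  # "age" or "education"
    family: str
    center: float

    def __post_init__(self) -> None:
        if self.predictor not in ("age", "education"):
            raise ConfigError(f"unknown predictor {self.predictor!r}")
        if self.family not in TRANSFORM_FAMILIES:
            raise ConfigError(f"unknown transform family {self.family!r}")
        if self.family in ("log", "reciprocal") and self.predictor != "education":
            raise ConfigError(f"{self.family} transform is education-only")
        if not np.isfinite(self.center):
            raise ConfigError("centering constant must be finite")


def eval_transform(spec: TransformSpec, value) -> np.ndarray | float:
    """Centered transformed predictor: T(value) - center."""
    x = np.asarray(value, dtype=float)
    if spec.family in ("log", "reciprocal") and np.any(x < 1):
        raise TransformDomainError(
            f"{spec.family}({spec.predictor}) requires values >= 1, got "
            f"{float(np.min(x))}")
    out = TRANSFORM_FAMILIES[spec.family](x) - spec.center
    return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out


@dataclass(frozen=True)
class AdjustmentEquation:
    """Per-scale demographic correction.

    ``age_coefficient`` and ``edu_coefficient`` are the adjustment
    coefficients as printed in normative tables (negated regression
    slopes).  ``fit_stats``, present when the equation was fitted, holds
    slopes, standardized betas, p-values, SSR and R^2.
    """

    scale: str
    age: TransformSpec
    age_coefficient: float
    education: TransformSpec
    edu_coefficient: float
    fit_stats: dict = field(default_factory=dict, compare=False)

    def adjustment(self, age, education):
        """Correction term added to the raw score."""
        return (self.age_coefficient * eval_transform(self.age, age)
                + self.edu_coefficient * eval_transform(self.education, education))

    def formula(self) -> str:
        """Printed-style equation text."""
        fam_txt = {"identity": "{p}", "square": "({p}^2)", "cube": "({p}^3)",
                   "log": "ln({p})", "reciprocal": "(1/{p})"}
        at = fam_txt[self.age.family].format(p="age")
        et = fam_txt[self.education.family].format(p="education")
        return (f"AS = RS + {self.age_coefficient:+g}*[{at}-{self.age.center:g}] "
                f"{self.edu_coefficient:+g}*[{et}-{self.education.center:g}]")


def adjust_score(raw, age, education, eq: AdjustmentEquation):
    """Adjusted score AS = RS + adjustment(age, education), unrounded."""
    return np.asarray(raw, dtype=float) + eq.adjustment(age, education) \
        if np.ndim(raw) else float(raw) + float(eq.adjustment(age, education))


def _design(ages, edus, age_family: str, edu_family: str):
    age_spec = TransformSpec("age", age_family, 0.0)
    edu_spec = TransformSpec("education", edu_family, 0.0)
    ta = eval_transform(age_spec, np.asarray(ages))
    te = eval_transform(edu_spec, np.asarray(edus))
    a_center = float(np.mean(ta))
    e_center = float(np.mean(te))
    return (TransformSpec("age", age_family, a_center), ta - a_center,
            TransformSpec("education", edu_family, e_center), te - e_center)


def fit_adjustment_arrays(ages, edus, scores, age_family: str, edu_family: str,
                          scale_name: str = "score") -> AdjustmentEquation:
    """OLS of scores on the two centered transformed predictors.

    Centering constants are the sample means of the transformed
    predictors.  Adjustment coefficients are the negated slopes.
    """
    y = np.asarray(scores, dtype=float)
    n = y.size
    if n < 4:
        raise SingularFitError(f"need n > 3 to fit two predictors, got n={n}")
    age_spec, xa, edu_spec, xe = _design(ages, edus, age_family, edu_family)
    X = sm.add_constant(np.column_stack([xa, xe]))
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError(
            f"degenerate design for ({age_family}, {edu_family}): collinear "
            "or constant predictors")
    res = sm.OLS(y, X).fit()
    sy = np.std(y, ddof=1)
    std_beta = (np.array([np.nan, np.std(xa, ddof=1), np.std(xe, ddof=1)])
                * res.params / sy if sy > 0 else np.full(3, np.nan))
    ci = res.conf_int(alpha=0.05)
    stats_ = {
        "n": int(n),
        "slopes": {"age": float(res.params[1]), "education": float(res.params[2])},
        "intercept": float(res.params[0]),
        "std_beta": {"age": float(std_beta[1]), "education": float(std_beta[2])},
        "p_values": {"age": float(res.pvalues[1]), "education": float(res.pvalues[2])},
        "conf_int": {"age": (float(ci[1][0]), float(ci[1][1])),
                     "education": (float(ci[2][0]), float(ci[2][1]))},
        "ssr": float(res.ssr),
        "r_squared": float(res.rsquared),
        "aic": float(res.aic),
        "abs_t": {"age": float(abs(res.tvalues[1])),
                  "education": float(abs(res.tvalues[2]))},
    }
    return AdjustmentEquation(scale_name, age_spec, -float(res.params[1]),
                              edu_spec, -float(res.params[2]), stats_)


def fit_adjustment(cohort: Cohort, scale: ScaleDefinition,
                   age_family: str = "cube", edu_family: str = "log",
                   ) -> AdjustmentEquation:
    """Fit the demographic adjustment for one FAB scale on a cohort."""
    y = cohort.scores()[scale.name].to_numpy(dtype=float)
    return fit_adjustment_arrays(cohort.df["age"], cohort.df["education"], y,
                                 age_family, edu_family, scale.name)


@dataclass
class SelectionReport:
    """Outcome of transform selection: the winning pair, its fitted
    equation, and the per-pair audit table."""

    age_family: str
    edu_family: str
    equation: AdjustmentEquation
    table: pd.DataFrame
    criterion: str


def select_transforms_arrays(ages, edus, scores,
                             age_candidates: Sequence[str] = DEFAULT_AGE_CANDIDATES,
                             edu_candidates: Sequence[str] = DEFAULT_EDU_CANDIDATES,
                             criterion: str = "ssr",
                             scale_name: str = "score") -> SelectionReport:
    if not age_candidates or not edu_candidates:
        raise ConfigError("need at least one candidate family per predictor")
    if criterion not in ("ssr", "aic", "min_abs_t"):
        raise ConfigError(f"unknown selection criterion {criterion!r}")
    rows = []
    fits: dict[tuple[str, str], AdjustmentEquation] = {}
    for af, ef in itertools.product(age_candidates, edu_candidates):
        try:
            eq = fit_adjustment_arrays(ages, edus, scores, af, ef, scale_name)
        except SingularFitError:
            continue
        fits[(af, ef)] = eq
        s = eq.fit_stats
        rows.append({"age_family": af, "edu_family": ef, "ssr": s["ssr"],
                     "aic": s["aic"], "r_squared": s["r_squared"],
                     "abs_t_age": s["abs_t"]["age"],
                     "abs_t_edu": s["abs_t"]["education"],
                     "p_age": s["p_values"]["age"],
                     "p_edu": s["p_values"]["education"]})
    if not fits:
        raise SingularFitError("every candidate transform pair was singular")
    table = pd.DataFrame(rows)
    if criterion in ("ssr", "aic"):
        key = table[criterion]
    else:  # largest minimum |t| across the two terms
        key = -np.minimum(table["abs_t_age"], table["abs_t_edu"])
    best = table.loc[key.idxmin()]
    af, ef = str(best["age_family"]), str(best["edu_family"])
    return SelectionReport(af, ef, fits[(af, ef)],
                           table.sort_values("ssr").reset_index(drop=True),
                           criterion)


def select_transforms(cohort: Cohort, scale: ScaleDefinition,
                      age_candidates: Sequence[str] = DEFAULT_AGE_CANDIDATES,
                      edu_candidates: Sequence[str] = DEFAULT_EDU_CANDIDATES,
                      criterion: str = "ssr") -> SelectionReport:
    """Fit every candidate (age, education) transform pair and return the
    pair optimizing ``criterion`` (residual sum of squares by default),
    with the full per-pair report retained for audit."""
    y = cohort.scores()[scale.name].to_numpy(dtype=float)
    return select_transforms_arrays(cohort.df["age"], cohort.df["education"], y,
                                    age_candidates, edu_candidates, criterion,
                                    scale.name)


@dataclass
class AdjustmentGrid:
    """Correction factors on an age x education lattice (display form)."""

    scale: str
    ages: tuple[int, ...]
    educations: tuple[int, ...]
    values: pd.DataFrame  # index = education, columns = age
    decimals: int

    def cell(self, age: int, education: int) -> float:
        return float(self.values.at[education, age])


def generate_grid(eq: AdjustmentEquation,
                  ages: Sequence[int] = DEFAULT_GRID_AGES,
                  educations: Sequence[int] = DEFAULT_GRID_EDUCATIONS,
                  decimals: int = 2) -> AdjustmentGrid:
    """Evaluate the adjustment on a lattice, rounding half-up for display."""
    if not len(ages) or not len(educations):
        raise ConfigError("grid lattices must be non-empty")
    vals = [[round_half_up(eq.adjustment(a, e), decimals) for a in ages]
            for e in educations]
    df = pd.DataFrame(vals, index=pd.Index(educations, name="education"),
                      columns=pd.Index(ages, name="age"))
    return AdjustmentGrid(eq.scale, tuple(ages), tuple(educations), df, decimals)


def compare_grid(grid: AdjustmentGrid, reference: pd.DataFrame,
                 atol: float = 0.01) -> pd.DataFrame:
    """Cell-by-cell comparison against a reference table.

    ``reference`` must share the grid's index/columns; NaN reference
    cells (illegible or known-anomalous in the source) are skipped.
    Returns a DataFrame of mismatches (empty when all legible cells agree
    within ``atol``).
    """
    rows = []
    for e in grid.educations:
        for a in grid.ages:
            ref = reference.at[e, a]
            if pd.isna(ref):
                continue
            got = grid.cell(a, e)
            if abs(got - float(ref)) > atol + 1e-12:
                rows.append({"scale": grid.scale, "education": e, "age": a,
                             "computed": got, "reference": float(ref)})
    return pd.DataFrame(rows, columns=["scale", "education", "age",
                                       "computed", "reference"])
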
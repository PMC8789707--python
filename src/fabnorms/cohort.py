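"""Cohort container, CSV I/O, descriptive statistics and the normality screen.

A cohort is one row per participant: demographics (sex, age in years,
education in completed school years), the six FAB item scores, the MoCA
total and its six sub-domain scores.  Education has a hard minimum of 1
because the demographic adjustment uses logarithmic and reciprocal
education transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CohortValidationError,
    ConfigError,
    DegenerateDataError,
    SchemaError,
)
from .scales import ALL_SCALES, ScaleDefinition, scale_scores

#: Canonical CSV column order.
MOCA_SUB_KEYS = ("EF", "A", "L", "M", "VS", "O")
MOCA_SUB_COLUMNS = tuple(f"moca_{k.lower()}" for k in MOCA_SUB_KEYS)
FAB_ITEM_COLUMNS = tuple(f"fab{i}" for i in range(1, 7))
SCHEMA_COLUMNS = (
    ("id", "sex", "age", "education")
    + FAB_ITEM_COLUMNS
    + ("moca_total",)
    + MOCA_SUB_COLUMNS
)

#: Sub-domain maxima used for validation.  The MoCA sums to 30; the
#: six-domain split declared here is a convention of this package's
#: synthetic data (see docs/methods.md) and is configurable.
DEFAULT_MOCA_DOMAIN_MAX: dict[str, int] = {
    "EF": 4, "A": 6, "L": 6, "M": 5, "VS": 3, "O": 6,
}

AGE_MIN, AGE_MAX = 18, 110
EDUCATION_MIN = 1


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject: demographics plus FAB items and MoCA scores.

    MoCA sub-scores may be missing (``None``); the record is still usable
    for FAB norming and is merely flagged for the correlation battery.
    """

    id: str
    sex: str  # "F" or "M"
    age: int
    education: int
    fab_items: tuple[int, ...]
    moca_total: int | None = None
    moca_sub: Mapping[str, int] = field(default_factory=dict)

    def problems(self, moca_max: Mapping[str, int] | None = None) -> list[str]:
        moca_max = moca_max or DEFAULT_MOCA_DOMAIN_MAX
        out = []
        if self.sex not in ("F", "M"):
            out.append(f"sex {self.sex!r} not in {{F, M}}")
        if not (AGE_MIN <= self.age <= AGE_MAX):
            out.append(f"age {self.age} outside {AGE_MIN}..{AGE_MAX}")
        if self.education < EDUCATION_MIN:
            out.append(f"education {self.education} < {EDUCATION_MIN}")
        if len(self.fab_items) != 6:
            out.append(f"{len(self.fab_items)} FAB items, expected 6")
        else:
            for i, v in enumerate(self.fab_items, start=1):
                if not (0 <= v <= 3):
                    out.append(f"fab{i} = {v} outside 0..3")
        if self.moca_total is not None and not (0 <= self.moca_total <= 30):
            out.append(f"moca_total {self.moca_total} outside 0..30")
        for k, v in self.moca_sub.items():
            if v is None:
                continue
            hi = moca_max.get(k)
            if hi is not None and not (0 <= v <= hi):
                out.append(f"moca_{k.lower()} = {v} outside 0..{hi}")
        return out


@dataclass
class Cohort:
    """Ordered participant table with provenance metadata.

    ``df`` holds one row per subject using the canonical column names in
    :data:`SCHEMA_COLUMNS` (extra columns, e.g. generator latents, are
    tolerated and ignored by I/O).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise CohortValidationError([(int(i), "id", f"duplicate id {dup!r}")
                                         for i in self.df.index[self.df["id"].duplicated()]])

    @property
    def n(self) -> int:
        return len(self.df)

    def scores(self) -> pd.DataFrame:
        """Raw FAB scale scores (total and sub-scales), one column each."""
        items = self.df[list(FAB_ITEM_COLUMNS)].to_numpy(dtype=int)
        out = {}
        for s in ALL_SCALES:
            idx = [i - 1 for i in s.item_indices]
            out[s.name] = items[:, idx].sum(axis=1)
        return pd.DataFrame(out, index=self.df.index)

    def records(self) -> Iterable[ParticipantRecord]:
        for _, row in self.df.iterrows():
            moca_sub = {}
            for key, col in zip(MOCA_SUB_KEYS, MOCA_SUB_COLUMNS):
                v = row[col]
                moca_sub[key] = None if pd.isna(v) else int(v)
            yield ParticipantRecord(
                id=str(row["id"]), sex=str(row["sex"]), age=int(row["age"]),
                education=int(row["education"]),
                fab_items=tuple(int(row[c]) for c in FAB_ITEM_COLUMNS),
                moca_total=None if pd.isna(row["moca_total"]) else int(row["moca_total"]),
                moca_sub=moca_sub,
            )


def _validate_frame(df: pd.DataFrame,
                    moca_max: Mapping[str, int]) -> list[tuple[int, str, str]]:
    problems: list[tuple[int, str, str]] = []

    def bad(mask, fieldname, msg_fmt):
        for i in df.index[np.asarray(mask)]:
            problems.append((int(i), fieldname, msg_fmt.format(v=df.at[i, fieldname])))

    bad(~df["sex"].isin(["F", "M"]), "sex", "value {v!r} not in {{F, M}}")
    bad((df["age"] < AGE_MIN) | (df["age"] > AGE_MAX), "age",
        "value {v} outside %d..%d" % (AGE_MIN, AGE_MAX))
    bad(df["education"] < EDUCATION_MIN, "education",
        "value {v} below minimum %d" % EDUCATION_MIN)
    for c in FAB_ITEM_COLUMNS:
        bad(df[c].isna() | (df[c] < 0) | (df[c] > 3), c, "value {v} outside 0..3")
    mt = df["moca_total"]
    bad(mt.notna() & ((mt < 0) | (mt > 30)), "moca_total", "value {v} outside 0..30")
    for key, c in zip(MOCA_SUB_KEYS, MOCA_SUB_COLUMNS):
        hi = moca_max.get(key)
        if hi is None:
            continue
        bad(df[c].notna() & ((df[c] < 0) | (df[c] > hi)), c,
            "value {v} outside 0..%d" % hi)
    return problems


def read_cohort(path: str | Path,
                schema: Mapping[str, str] | None = None,
                moca_max: Mapping[str, int] | None = None,
                on_invalid: str = "raise") -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional map from canonical column names to the file's column
        names, for files using different headers.
    on_invalid:
        ``"raise"`` (default) aborts with row-indexed diagnostics;
        ``"drop"`` removes offending rows and records the diagnostics in
        ``Cohort.provenance``.
    """
    moca_max = moca_max or DEFAULT_MOCA_DOMAIN_MAX
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read cohort CSV {path}: {exc}") from exc
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {', '.join(missing)}")
    df = df[list(SCHEMA_COLUMNS)].copy()
    df["id"] = df["id"].astype(str)
    for c in ("age", "education") + FAB_ITEM_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("moca_total",) + MOCA_SUB_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    # non-parseable required numerics surface as NaN -> validation errors
    problems = []
    for c in ("age", "education"):
        for i in df.index[df[c].isna()]:
            problems.append((int(i), c, "missing or non-numeric value"))
    problems += _validate_frame(df.fillna({c: -1 for c in ("age", "education")}),
                                moca_max)
    problems = sorted(set(problems))
    if problems:
        if on_invalid == "raise":
            raise CohortValidationError(problems)
        if on_invalid != "drop":
            raise ConfigError(f"on_invalid must be 'raise' or 'drop', got {on_invalid!r}")
        bad_rows = {r for r, _, _ in problems}
        df = df.drop(index=list(bad_rows)).reset_index(drop=True)
    for c in ("age", "education") + FAB_ITEM_COLUMNS:
        df[c] = df[c].astype(int)
    note = f"; dropped {len(problems)} invalid rows" if problems else ""
    return Cohort(df, provenance=f"read:{path}{note}")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical columns to CSV (UTF-8, comma-separated)."""
    cohort.df[list(SCHEMA_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stratification and descriptives

#: Default age and education bins: closed intervals mirroring the usual
#: normative-sample stratification layout.
DEFAULT_AGE_BINS = ((-math.inf, 35), (36, 45), (46, 55), (56, 65),
                    (66, 75), (76, 85), (86, 95), (96, math.inf))
DEFAULT_EDU_BINS = ((-math.inf, 5), (6, 11), (12, 16), (17, 21), (22, math.inf))


def _bin_label(lo: float, hi: float) -> str:
    if lo == -math.inf:
        return f"<={hi:g}"
    if hi == math.inf:
        return f">{lo - 1:g}"
    return f"{lo:g}-{hi:g}"


def _check_bins(bins: Sequence[tuple[float, float]], what: str) -> None:
    for lo, hi in bins:
        if lo > hi:
            raise ConfigError(f"{what} bin ({lo}, {hi}) is empty")
    ordered = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if lo2 <= hi1:
            raise ConfigError(f"overlapping {what} bins ({lo1},{hi1}) and ({lo2},{hi2})")


def stratification_table(cohort: Cohort,
                         age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
                         edu_bins: Sequence[tuple[float, float]] = DEFAULT_EDU_BINS,
                         ) -> pd.DataFrame:
    """Male/female counts per (education bin x age bin) cell.

    Returns a DataFrame indexed by education bin with a (age bin, sex)
    column MultiIndex; cell counts sum to the cohort size.
    """
    _check_bins(age_bins, "age")
    _check_bins(edu_bins, "education")

    def assign(values, bins, what):
        labels = np.full(len(values), None, dtype=object)
        for lo, hi in bins:
            m = (values >= lo) & (values <= hi)
            labels[np.asarray(m)] = _bin_label(lo, hi)
        if any(l is None for l in labels):
            v = values[np.array([l is None for l in labels])].iloc[0]
            raise ConfigError(f"{what} value {v} not covered by the given bins")
        return labels

    df = cohort.df
    age_labels = [_bin_label(*b) for b in sorted(age_bins)]
    edu_labels = [_bin_label(*b) for b in sorted(edu_bins)]
    cols = pd.MultiIndex.from_product([age_labels, ["M", "F"]], names=["age", "sex"])
    table = pd.DataFrame(0, index=pd.Index(edu_labels, name="education"), columns=cols)
    if len(df):
        a = assign(df["age"], age_bins, "age")
        e = assign(df["education"], edu_bins, "education")
        for ai, ei, s in zip(a, e, df["sex"]):
            table.loc[ei, (ai, s)] += 1
    return table


def descriptives(cohort: Cohort, variables: Sequence[str]) -> pd.DataFrame:
    """Per-variable n, mean, sd, min, max, skewness and excess kurtosis.

    ``variables`` may name cohort columns or derived FAB scale scores
    (``FAB``, ``FAB1``, ``FAB2``, ``FAB3``).  Missing values are dropped
    per variable.  Zero-variance variables get NaN shape statistics and
    a ``degenerate`` flag instead of an error.
    """
    score_df = cohort.scores()
    rows = []
    for v in variables:
        if v in score_df.columns:
            x = score_df[v].astype(float)
        elif v in cohort.df.columns:
            x = pd.to_numeric(cohort.df[v], errors="coerce")
        else:
            raise SchemaError(f"unknown variable {v!r}")
        x = x.dropna().to_numpy(dtype=float)
        if x.size < 2:
            raise DegenerateDataError(
                f"variable {v!r}: need n >= 2 for a standard deviation, got {x.size}")
        sd = float(np.std(x, ddof=1))
        degenerate = sd == 0.0
        if degenerate or x.size < 3:
            sk = ku = float("nan")
        else:
            sk = float(stats.skew(x, bias=False))
            ku = float(stats.kurtosis(x, fisher=True, bias=False))
        rows.append({"variable": v, "n": int(x.size), "mean": float(np.mean(x)),
                     "sd": sd, "min": float(np.min(x)), "max": float(np.max(x)),
                     "skewness": sk, "kurtosis": ku, "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("variable")


@dataclass(frozen=True)
class NormalityScreen:
    """Result of the distribution-shape screen on one variable."""

    skewness: float
    kurtosis: float
    kurtosis_convention: str  # "excess" or "raw"
    abnormal: bool
    degenerate: bool = False


def normality_screen(values: Sequence[float],
                     skew_threshold: float = 1.0,
                     kurt_threshold: float = 3.0,
                     kurtosis: str = "excess") -> NormalityScreen:
    """Screen a variable's distribution shape.

    The variable is flagged abnormal when |skewness| >= ``skew_threshold``
    or |kurtosis| >= ``kurt_threshold``.  Skewness is the adjusted
    Fisher-Pearson coefficient; the kurtosis statistic is excess kurtosis
    by default (``kurtosis="raw"`` switches to the non-excess convention,
    for which a normal distribution sits at 3).
    """
    if kurtosis not in ("excess", "raw"):
        raise ConfigError(f"kurtosis convention must be 'excess' or 'raw', got {kurtosis!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDataError(f"need n >= 3 for the normality screen, got {x.size}")
    if np.std(x, ddof=1) == 0.0:
        return NormalityScreen(float("nan"), float("nan"), kurtosis,
                               abnormal=False, degenerate=True)
    sk = float(stats.skew(x, bias=False))
    ku = float(stats.kurtosis(x, fisher=True, bias=False))
    if kurtosis == "raw":
        ku = ku + 3.0
    abnormal = abs(sk) >= skew_threshold or abs(ku) >= kurt_threshold
    return NormalityScreen(sk, ku, kurtosis, abnormal=abnormal)
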
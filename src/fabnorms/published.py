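"""The shipped normative constants (adjustment equations and ES tables)
and subject scoring against them.

The constants reproduce the published Italian adult norms for the FAB
and its three sub-scales: four demographic adjustment equations (cubic
age with logarithmic education for FAB total and FAB-1; cubic age with
reciprocal education for FAB-2; quadratic age with logarithmic education
for FAB-3) and the four tolerance-limit / equivalent-score rows.  They
are stored in a checked-in YAML file and checksum-verified at load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .adjustment import AdjustmentEquation, TransformSpec, round_half_up
from .cohort import Cohort, FAB_ITEM_COLUMNS, read_cohort
from .errors import CohortValidationError, FabNormsError, IntegrityError
from .norming import ES_LABELS, ESLevel, NormTable, classify_es
from .scales import ALL_SCALES, SCALES_BY_NAME, all_scale_scores

_DATA_PACKAGE = "fabnorms.data"
_DATA_FILE = "published_norms.yaml"

#: demographic extent of the published display grids; outside it the
#: continuous equations still apply but a warning is attached
GRID_AGE_RANGE = (35, 95)
GRID_EDU_RANGE = (5, 21)


@dataclass(frozen=True)
class PublishedNormSet:
    """The four shipped adjustment equations and norm tables."""

    equations: Mapping[str, AdjustmentEquation]
    tables: Mapping[str, NormTable]
    provenance: str

    def scale_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in ALL_SCALES)


def _canonical_checksum(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def load_published(path: str | Path | None = None) -> PublishedNormSet:
    """Load the shipped norms, verifying their checksum.

    ``path`` overrides the packaged file (used by tests and for future
    norm editions).
    """
    if path is None:
        text = resources.files(_DATA_PACKAGE).joinpath(_DATA_FILE).read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    doc = yaml.safe_load(text)
    stored = doc.pop("checksum", None)
    if stored is None or _canonical_checksum(doc) != stored:
        raise IntegrityError("published norm constants fail checksum verification")
    equations = {}
    for name, eq in doc["equations"].items():
        equations[name] = AdjustmentEquation(
            name,
            TransformSpec("age", eq["age"]["family"], float(eq["age"]["center"])),
            float(eq["age"]["coefficient"]),
            TransformSpec("education", eq["education"]["family"],
                          float(eq["education"]["center"])),
            float(eq["education"]["coefficient"]),
        )
    tables = {}
    for name, t in doc["norm_tables"].items():
        tables[name] = NormTable(
            scale=name, n=int(t["n"]), oTL=float(t["oTL"]), iTL=float(t["iTL"]),
            median=float(t["median"]), t1=float(t["t1"]), t2=float(t["t2"]),
            scheme=str(t.get("scheme", "published")),
            precision=int(t.get("precision", 2)))
    return PublishedNormSet(equations, tables, str(doc.get("provenance", "")))


@dataclass(frozen=True)
class ScaleScore:
    """One scale's scoring outcome for a subject."""

    scale: str
    raw: int
    adjusted: float
    es: int
    label: str


@dataclass(frozen=True)
class SubjectReport:
    age: int
    education: int
    sex: str | None
    results: Mapping[str, ScaleScore]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def score_subject(age: int, education: int,
                  fab_items: Sequence[int] | None = None,
                  raw_scores: Mapping[str, int] | None = None,
                  norms: PublishedNormSet | None = None,
                  sex: str | None = None) -> SubjectReport:
    """Score one subject against the shipped norms.

    Provide either the six FAB item scores (all four scales are scored)
    or a mapping of per-scale raw scores (only those scales are scored).
    Ages outside 35-95 or educations outside 5-21 are scored through the
    continuous equations with a warning, since the published grids are a
    display convenience only.
    """
    norms = norms or load_published()
    if (fab_items is None) == (raw_scores is None):
        raise FabNormsError("provide exactly one of fab_items or raw_scores")
    if fab_items is not None:
        raw_scores = all_scale_scores(fab_items)
    else:
        raw_scores = dict(raw_scores)
        for name, raw in raw_scores.items():
            scale = SCALES_BY_NAME.get(name)
            if scale is None:
                raise FabNormsError(f"unknown scale {name!r}")
            if not (scale.min_score <= int(raw) <= scale.max_score):
                raise CohortValidationError(
                    [(0, name, f"raw score {raw} outside "
                               f"{scale.min_score}..{scale.max_score}")])
    if education < 1:
        raise CohortValidationError([(0, "education", "education must be >= 1")])
    warnings = []
    if not (GRID_AGE_RANGE[0] <= age <= GRID_AGE_RANGE[1]):
        warnings.append(f"age {age} outside the published grid extent "
                        f"{GRID_AGE_RANGE[0]}-{GRID_AGE_RANGE[1]}; "
                        "scored via the continuous equation")
    if not (GRID_EDU_RANGE[0] <= education <= GRID_EDU_RANGE[1]):
        warnings.append(f"education {education} outside the published grid "
                        f"extent {GRID_EDU_RANGE[0]}-{GRID_EDU_RANGE[1]}; "
                        "scored via the continuous equation")
    results = {}
    for name, raw in raw_scores.items():
        eq = norms.equations[name]
        adj = float(raw) + float(eq.adjustment(age, education))
        es = classify_es(round_half_up(adj, norms.tables[name].precision),
                         norms.tables[name])
        results[name] = ScaleScore(name, int(raw), adj, es.level, es.label)
    return SubjectReport(int(age), int(education), sex, results,
                         tuple(warnings))


def batch_score(cohort: Cohort | str | Path,
                norms: PublishedNormSet | None = None,
                out: str | Path | None = None) -> pd.DataFrame:
    """Score every cohort row; row-level failures are reported in an
    ``error`` column and the run continues.  Deterministic."""
    norms = norms or load_published()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort, on_invalid="drop")
    rows = []
    for _, r in cohort.df.iterrows():
        base = {"id": r["id"], "sex": r["sex"], "age": r["age"],
                "education": r["education"]}
        try:
            items = [int(r[c]) for c in FAB_ITEM_COLUMNS]
            rep = score_subject(int(r["age"]), int(r["education"]),
                                fab_items=items, norms=norms, sex=str(r["sex"]))
            for name, sc in rep.results.items():
                base[f"{name}_raw"] = sc.raw
                base[f"{name}_adjusted"] = round_half_up(sc.adjusted, 2)
                base[f"{name}_es"] = sc.es
                base[f"{name}_label"] = sc.label
            base["warnings"] = "; ".join(rep.warnings)
            base["error"] = ""
        except FabNormsError as exc:
            base["error"] = str(exc).splitlines()[0]
        rows.append(base)
    cols = ["id", "sex", "age", "education"]
    for s in ALL_SCALES:
        cols += [f"{s.name}_raw", f"{s.name}_adjusted", f"{s.name}_es",
                 f"{s.name}_label"]
    cols += ["warnings", "error"]
    df = pd.DataFrame(rows, columns=cols)
    if out is not None:
        df.to_csv(out, index=False)
    return df
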
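#!/usr/bin/env python
"""Step 4 — tolerance limits and equivalent-score thresholds.

Adjusts each scale's raw scores with the fitted equations from step 3,
derives outer/inner tolerance limits on the 5th centile and the ES 0-4
interval boundaries, and prints them next to the shipped published rows.
Finally batch-scores the cohort against the published norms.
"""

import json
from pathlib import Path

from fabnorms import (
    batch_score,
    compute_norm_table,
    load_published,
    read_cohort,
)
from fabnorms.adjustment import AdjustmentEquation, TransformSpec
from fabnorms.scales import ALL_SCALES

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "synthetic_cohort.csv")
    fitted = json.loads((RESULTS / "fitted_equations.json").read_text())
    norms = load_published()
    scores = cohort.scores()
    tables = {}
    for scale in ALL_SCALES:
        f = fitted[scale.name]
        eq = AdjustmentEquation(
            scale.name,
            TransformSpec("age", f["age_family"], f["age_center"]),
            f["age_coefficient"],
            TransformSpec("education", f["edu_family"], f["edu_center"]),
            f["edu_coefficient"])
        adj = scores[scale.name].to_numpy(float) + eq.adjustment(
            cohort.df.age.to_numpy(float), cohort.df.education.to_numpy(float))
        table = compute_norm_table(adj, scale.name)
        tables[scale.name] = table.to_dict()
        pub = norms.tables[scale.name]
        print(f"{scale.name:>5}: derived oTL {table.oTL:6.2f} iTL {table.iTL:6.2f} "
              f"Mdn {table.median:6.2f} | published oTL {pub.oTL:6.2f} "
              f"iTL {pub.iTL:6.2f} Mdn {pub.median:6.2f}")
    (RESULTS / "derived_norm_tables.json").write_text(json.dumps(tables, indent=2))

    report = batch_score(cohort, norms=norms, out=RESULTS / "scored_cohort.csv")
    dist = report["FAB_es"].value_counts().sort_index()
    print("ES distribution of the cohort under the published norms:")
    for level, count in dist.items():
        print(f"  ES {level}: {count:4d}  ({count / len(report):.1%})")


if __name__ == "__main__":
    main()
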
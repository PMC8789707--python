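#!/usr/bin/env python
"""Step 5 — convergent validity, sex effects, and the power analysis.

Runs the Bonferroni-controlled FAB x MoCA Spearman battery (k = 28,
adjusted alpha 0.05/28), the sub-scale intercorrelations, per-scale sex
t-tests with a variance-homogeneity pretest, and the noncentral-F
minimum-sample-size computation for the norming regressions.
"""

from pathlib import Path

import pandas as pd

from fabnorms import (
    correlation_battery,
    min_sample_size,
    read_cohort,
    sex_tests,
    subscale_battery,
)
from fabnorms.validation import battery_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "synthetic_cohort.csv")

    battery = battery_frame(correlation_battery(cohort))
    battery.to_csv(RESULTS / "correlation_battery.tsv", sep="\t", index=False)
    sig = battery[battery.significant]
    import math

    alpha4 = math.floor(battery.alpha_adjusted.iloc[0] * 1e4) / 1e4
    print(f"FAB x MoCA battery: {len(battery)} pairs, "
          f"alpha_adjusted = {alpha4} (0.05/{len(battery)}), "
          f"{len(sig)} significant")
    top = battery.loc[battery.coefficient.abs().idxmax()]
    print(f"  strongest: {top.x} ~ {top.y}  r_s = {top.coefficient:.2f}")

    subs = battery_frame(subscale_battery(cohort))
    subs.to_csv(RESULTS / "subscale_battery.tsv", sep="\t", index=False)
    print("sub-scale structure (Spearman):")
    for _, r in subs.iterrows():
        print(f"  {r.x} ~ {r.y}: {r.coefficient:+.2f}")

    sex = pd.DataFrame([s.__dict__ for s in sex_tests(cohort)])
    sex.to_csv(RESULTS / "sex_tests.tsv", sep="\t", index=False)
    print("sex differences (t-tests):")
    for _, r in sex.iterrows():
        kind = "pooled" if r.pooled else "Welch"
        print(f"  {r.scale}: t({r.df:.1f}) = {r.t:+.2f}, p = {r.p_value:.3f} ({kind})")

    n_min = min_sample_size(u=3, f2=0.05, alpha=0.05, power=0.9)
    print(f"minimum N for the norming regressions "
          f"(u=3, f2=0.05, alpha=0.05, power=0.90): {n_min}")


if __name__ == "__main__":
    main()
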
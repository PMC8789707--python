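#!/usr/bin/env python
"""Step 2 — describe the cohort and screen distribution shapes.

Produces the sample-stratification table (sex counts per age x education
cell), per-variable descriptives, and the skewness/kurtosis normality
screen (abnormal when |skewness| >= 1 or |excess kurtosis| >= 3).
"""

from pathlib import Path

from fabnorms import descriptives, normality_screen, read_cohort, stratification_table

RESULTS = Path(__file__).resolve().parent.parent / "results"

VARIABLES = ["age", "education", "moca_total", "FAB", "FAB1", "FAB2", "FAB3"]


def main() -> None:
    cohort = read_cohort(RESULTS / "synthetic_cohort.csv")

    strat = stratification_table(cohort)
    strat.to_csv(RESULTS / "stratification.csv")
    print("stratification (rows sum to n =", cohort.n, ")")

    desc = descriptives(cohort, VARIABLES)
    desc.to_csv(RESULTS / "descriptives.csv")
    print(desc[["n", "mean", "sd", "min", "max"]].round(2).to_string())

    rows = []
    scores = cohort.scores()
    for v in VARIABLES:
        x = scores[v] if v in scores.columns else cohort.df[v].astype(float)
        res = normality_screen(x.dropna())
        rows.append((v, res.skewness, res.kurtosis, res.abnormal))
        flag = "ABNORMAL" if res.abnormal else "ok"
        print(f"  shape {v:>10}: skew {res.skewness:+.2f}  kurt {res.kurtosis:+.2f}  {flag}")
    import pandas as pd

    pd.DataFrame(rows, columns=["variable", "skewness", "kurtosis", "abnormal"]) \
        .to_csv(RESULTS / "normality_screen.csv", index=False)


if __name__ == "__main__":
    main()
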
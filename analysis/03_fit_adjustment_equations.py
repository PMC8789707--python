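#!/usr/bin/env python
"""Step 3 — select demographic transforms and fit adjustment equations.

For each FAB scale, fits all candidate (age, education) transform pairs
— age in {identity, square, cube}, education in {identity, log,
reciprocal} — keeps the pair with the smallest residual sum of squares,
and writes the fitted adjustment equation plus its age x education
correction grid.  Also regenerates the published grids from the shipped
equations for side-by-side comparison.
"""

import json
from pathlib import Path

from fabnorms import generate_grid, load_published, read_cohort, select_transforms
from fabnorms.scales import ALL_SCALES

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "synthetic_cohort.csv")
    norms = load_published()
    fitted = {}
    for scale in ALL_SCALES:
        sel = select_transforms(cohort, scale)
        eq = sel.equation
        s = eq.fit_stats
        fitted[scale.name] = {
            "age_family": sel.age_family, "edu_family": sel.edu_family,
            "age_coefficient": eq.age_coefficient,
            "edu_coefficient": eq.edu_coefficient,
            "age_center": eq.age.center, "edu_center": eq.education.center,
            "std_beta": s["std_beta"], "p_values": s["p_values"],
            "r_squared": s["r_squared"],
        }
        print(f"{scale.name}: selected ({sel.age_family}, {sel.edu_family}); "
              f"beta_age = {s['std_beta']['age']:+.2f}, "
              f"beta_edu = {s['std_beta']['education']:+.2f}, "
              f"R^2 = {s['r_squared']:.3f}")
        generate_grid(eq).values.to_csv(RESULTS / f"grid_fitted_{scale.name}.tsv",
                                        sep="\t")
        generate_grid(norms.equations[scale.name]).values.to_csv(
            RESULTS / f"grid_published_{scale.name}.tsv", sep="\t")
    (RESULTS / "fitted_equations.json").write_text(json.dumps(fitted, indent=2))
    print("wrote fitted_equations.json and per-scale grids")


if __name__ == "__main__":
    main()
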
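# Methods

This note documents the statistical model behind `fabnorms`, the
choices made where the methodology admits more than one convention, and
what the synthetic cohort does and does not establish.

## The norming model

### Demographic adjustment

Raw scale scores RS are adjusted by a two-term regression correction,

    AS = RS + c_age·[T_age(age) − m_age] + c_edu·[T_edu(edu) − m_edu],

fitted by ordinary least squares of RS on the two centered, transformed
predictors simultaneously.  The centering constants m are the sample
means of the transformed predictors, so the adjustment vanishes for the
"average" subject and AS equals RS there.  The adjustment coefficients
c are the negated fitted slopes: the correction *removes* the estimated
demographic effect.  Internally the fitted slope is the stored primitive
and the printed-style equation is derived from it, which avoids
double-negation mistakes when round-tripping equations through files.

Candidate transform families are identity/square/cube for age and
identity/log/reciprocal for education.  Log and reciprocal education
require at least one year of schooling; education 0 is rejected rather
than imputed, matching the 1–25-year range of the reference sample.

**Transform selection.**  "Most predictive pair" is operationalized as
the pair minimizing the residual sum of squares, which with a constant
predictor count (always 1 age + 1 education term) is equivalent to
maximizing R² and, up to monotone transformation, to maximizing the
F-statistic of the two-term model.  Alternative criteria (AIC, largest
minimum |t|) are selectable; the full per-pair audit table is always
returned.  A caveat documented here because it matters in practice: the
age families are extremely collinear (corr(age², age³) > 0.99 over ages
21–96), so at realistic noise levels neighbouring families are often
statistically indistinguishable and selection among them is unstable.
The fitted correction, however, is nearly identical whichever
neighbouring family wins — the instability affects the label, not the
adjustment.

**Grids.**  The age × education correction grids are a display
convenience: cells are the adjustment at raw score 0, rounded half-up
at 2 decimals, on the conventional lattice (ages 35–95 by 5; educations
5, 8, 11, 13, 16, 18, 21).  Scoring outside the lattice uses the
continuous equation and attaches a warning rather than refusing, since
the equations are defined on the full demographic range.

### Tolerance limits and equivalent scores

For sample size n and centile q (default 0.05), the r-th order
statistic is below the population q-centile with probability
P(Binomial(n, q) ≥ r).  The outer tolerance limit takes the largest r
with that probability ≥ 0.95; the inner limit the smallest s with it
≤ 0.05.  For n = 475 these are ranks 16 and 33.  At small n (e.g.
n = 20) no rank satisfies the outer condition and norm derivation fails
explicitly rather than silently degrading.  Ties at the rank position
take the observation's value (ties broken by value, not index).

Equivalent scores: ES 0 is AS ≤ oTL; ES 4 is AS > median (strict, so an
AS exactly at the median is ES 3); ES 1–3 partition (oTL, median] by
two inner thresholds t1 < t2, all intervals closed on the right.  The
method literature does not fix a single construction for t1 and t2, so
two labelled schemes are shipped and neither is claimed to be the
original authors':

* `z-intervals` (default): the z-interval [z(0.05), 0] is cut into
  equal thirds; the cuts map to empirical centiles ≈ 13.6% and 29.2%,
  realized as order statistics at ranks ⌈p·n⌉.
* `equal-count`: thresholds at ranks evenly spaced between the outer
  rank and the median rank.

The published ES tables are shipped verbatim, so the scheme choice only
affects newly derived norms.  Classification against a published
(display-precision) table first rounds the AS to the table's precision
half-up, so interval endpoints behave exactly as printed.

### Shipped published norms

The four adjustment equations and four ES rows live in
`src/fabnorms/data/published_norms.yaml`.  The loader recomputes a
SHA-256 checksum over the canonical JSON serialization of the payload
and refuses tampered files.  Regenerating the printed correction grids
from these equations reproduces every legible printed cell exactly at
2-decimal rounding; eight cells (four two-cell runs adjacent to
zero-valued entries: FAB-1 education 8 ages 45–50, FAB-1 education 16
ages 80–85, FAB-2 education 21 ages 70–75, FAB-3 education 18 ages
85–90) are garbled in the printed source and are excluded and logged
(`tests/data/printed_grid_anomalies.csv`).  For the flagged FAB-2 run
the formula yields ≈ 0.00 and 0.16 where the printed row shows a
non-monotone pair; the formula is trusted.

## Validation statistics

* **Correlation battery.**  Spearman by default (average ranks for
  ties, t-approximation p-values — the n = 475 regime), pairwise-
  complete observations, Bonferroni control with k = number of pairs
  (4 FAB × 7 MoCA measures = 28, adjusted α = 0.05/28, i.e. 0.0017 at
  4-decimal truncation).  Zero-variance variables yield an explicit
  undefined-coefficient flag.
* **Sex tests.**  Two-sample t per scale; a two-sided F-ratio
  variance-homogeneity pretest at α = 0.05 switches to the Welch
  unequal-variance test (fractional df) when it rejects — this mixed
  integer/fractional-df policy mirrors standard normative practice and
  is configurable.
* **Power analysis.**  Minimum n for the regression F-test with u
  numerator df, Cohen effect size f², via the noncentral F distribution
  with denominator df v = n − u − 1 and noncentrality λ = f²·(u + v + 1)
  = f²·n.  The power equation is solved continuously in n (the
  convention of the standard power tools, which treat v as real-valued)
  and reported at the nearest whole participant: for (u = 3, f² = 0.05,
  α = 0.05, power 0.9) the continuous solution is n* ≈ 287.4 → 287.
  A strict mode (`rounding="ceil"`) instead returns the smallest
  integer n whose power actually meets the target (288 here) and
  satisfies the bracketing property power(n) ≥ target > power(n − 1).

## Normality screen

Adjusted Fisher–Pearson skewness and excess kurtosis, flagged abnormal
at |skew| ≥ 1 or |kurtosis| ≥ 3.  Excess kurtosis is the default
convention because the |3| rule is meaningful only on that scale (raw
kurtosis of a normal distribution is already 3, so a raw-scale |3| rule
would flag half of all normal samples); a `kurtosis="raw"` switch is
provided for audit against sources using the non-excess convention.
Zero-variance input returns an explicit degenerate result.  The screen
runs on raw variables.

## The synthetic cohort

The generator emulates the reference sample's structure, not any
individual's data:

* **Demographics.**  (age, education) from a truncated bivariate
  normal — means 61.08 and 11.67 years, SDs 15.1 and 4.57, ranges
  21–96 and 1–25, correlation −0.45 (older participants skew less
  educated, the qualitative shape of the sample's stratification) —
  rounded to integer years.  Sex is assigned by deterministic count
  (round(n·306/475) females, randomly ordered), so the default cohort
  reproduces the 306/169 margin exactly.
* **FAB scores.**  Each sub-scale has a latent Gaussian model:
  intercept + age effect + education effect + shared general-
  performance factor + noise.  The age/education betas are the negated
  published adjustment coefficients (so refitting the pipeline on
  synthetic data lands near the published equations); intercepts
  (5.430, 6.515, 6.055), the shared loading (0.65) and noise SDs
  (0.942, 1.965, 1.800) were calibrated once against the reference
  sample moments (sub-scale means 5.21/5.41/5.27, SDs 0.93/1.08/1.14,
  total 15.9 ± 2.17) and are fixed defaults.  Latents are rounded,
  clipped to 0–6, and split across the two items as evenly as possible
  (largest-remainder apportionment: deterministic, total-preserving).
  Subjects below the healthy floors observed in the reference sample
  (total < 9, FAB-1 < 1, FAB-3 < 1) have their noise redrawn —
  emulating the health screening that shaped the sample's ranges.
  Sex has no score effect, matching the absence of sex differences.
* **MoCA.**  Total = mixture of the standardized FAB latent and
  independent noise, scaled to 24.5 ± 3.95 and floored at 8; the
  mixing weight maps the target Spearman coupling (default 0.49)
  through the bivariate-normal rank-correlation identity with a fixed
  ×1/0.85 attenuation correction for rounding/clipping.  Sub-domain
  scores allocate the total proportionally to declared domain maxima
  (EF 4, A 6, L 6, M 5, VS 3, O 6 — a convention of this package, as
  the domain split is not standardized) with small jitter; the EF
  domain borrows part of the shared factor so its FAB coupling is the
  strongest, as in real data.

**What the generator does not reproduce**, and hence what passing tests
on synthetic data do and do not show: it does not reproduce the exact
joint age × education cell counts, the empirical FAB–MoCA correlation
matrix, the fitted standardized betas, or the published oTL/iTL values
— all of which depend on the raw participant data.  Synthetic-data
tests therefore check *properties* (effect directions, part–whole
correlation ordering, tolerance-limit proximity at loose tolerance),
while exact tests are reserved for the published constants themselves.
Because rounding and ceiling-clipping bias regression estimates by
construction, parameter-recovery oracles fit on the generator's
retained continuous latent columns; the discretized item scores remain
the cohort's observable data.

## Numerical choices

* Grid rounding half-up at 2 decimals (display); full precision kept
  internally; adjustment is exactly affine in RS with unit slope.
* Tolerance ranks via vectorized survival-function evaluation; verified
  against an explicit cumulative-pmf tail scan for every n ≤ 2000.
* The degenerate cases are explicit: constant adjusted scores give a
  flagged degenerate norm table; zero-variance screen input a flagged
  degenerate result; singular designs a `SingularFitError`; absent
  outer rank a `NormsUnderivableError`.
* Monte-Carlo test sizes (200 replicates for parameter recovery, 500
  for coverage, n = 475 per replicate) match the study's sample size
  while keeping the suite fast; all test randomness is seeded.

## Known limitations

* The ES 1–3 inner-threshold construction is not uniquely determined by
  the method literature; both shipped schemes are labelled and the
  published tables are used verbatim for classification.
* Transform selection among near-collinear families is intrinsically
  unstable at realistic noise (see above); consumers should read the
  audit table, not just the winning label.
* The MoCA sub-domain maxima are a declared convention, and MoCA
  sub-scores are not norm-adjusted (MoCA norming is out of scope).
* The scorer performs psychometric classification only; it makes no
  diagnostic claims.
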
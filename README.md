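# vo2ref

Age- and sex-specific reference values for maximum oxygen uptake relative
to body mass (VO2max/kg, ml·min⁻¹·kg⁻¹) from cycle-ergometry
cardiopulmonary exercise testing (CPET).

A measured VO2max is only interpretable against what is *normal* for a
subject's age and sex. `vo2ref` implements the full reference-value
construction pipeline used for fitness-registry cohorts, for exercise
physiologists and biostatisticians who build or evaluate such norms:

1. **Effort screening** — keep only true maximal tests: respiratory
   exchange ratio ≥ 1.0 and HRmax ≥ 85% of the Tanaka prediction
   (208 − 0.7 × age), after excluding athletes, smokers and BMI > 30.
2. **LMS centile curves** — model the age-conditional distribution of
   VO2max/kg by the Box-Cox Cole-Green family: three cubic-spline curves
   L(t) (skewness), M(t) (median), S(t) (coefficient of variation) fitted
   by penalised maximum likelihood, so that
   z = ((y/M)^L − 1)/(L·S) is standard normal and the p-th centile is the
   inverse transform at Φ⁻¹(p). Centiles P3 (lower limit of normal), P10,
   P25, P50, P75, P90 and P97 (upper limit of normal) are tabulated.
3. **Reference equations** — polynomial trendlines in age (with R² and
   SEE) extracted from the P3/P50/P97 curves; e.g. the male median is
   VO2max/kg = −0.0049·age² + 0.0884·age + 48.263.
4. **Comparison with published norms** — Jones, Wasserman and Cooper
   equations evaluated per kilogram (using per-stratum mean body weights
   where a formula predicts absolute VO2max) on a common model × age grid.
5. **Cross-validation** — paired t-test of measured vs predicted values
   on a holdout cohort (positive mean difference = equation
   over-predicts).

No registry data are distributed; a seeded synthetic-cohort generator
(`vo2ref.cohort`) reproduces the registry's *structure* — ~3.9:1
male:female, ages 6–65 concentrated in the working decades, published
per-stratum anthropometrics, BCCG-distributed VO2max/kg, and a
configurable fraction of submaximal tests — so the whole pipeline runs
and is tested end-to-end. See `docs/methods.md` for models, numerical
choices and limitations.

## Worked example

```python
from vo2ref import (classify_vs_limits, evaluate, percent_predicted,
                    round_half_up)

pred = evaluate("lowlands", "male", 20)        # study median equation
print(round_half_up(pred, 1))                  # 48.1  ml/min/kg
print(round(percent_predicted(40.0, pred), 1)) # 83.2  % of predicted
print(classify_vs_limits(30.0, "male", 20.0).value)  # below_lln
```

A 20-year-old male with a measured VO2max of 40 ml·min⁻¹·kg⁻¹ sits at
83.2% of the predicted median (48.1); a value of 30 falls below the lower
limit of normal (P3 ≈ 36.0 at that age).

The same pipeline from the shell, on a synthetic cohort:

```
$ vo2ref predict --model lowlands --sex male --age 20
48.1
$ vo2ref simulate --n 1500 --seed 3 --submaximal-fraction 0.1 --out cohort.csv
$ vo2ref filter --input cohort.csv --out kept.csv
$ vo2ref fit-lms --input kept.csv --sex male --out curves.csv
$ vo2ref centiles --curves curves.csv --out centiles.csv
$ vo2ref trend --centiles centiles.csv --percentile P50 --degree 2 --out trend.csv
R^2 = 0.9966, SEE = 0.2355
```

The numbered scripts under `analysis/` run the complete study on the
default synthetic registry (4612 subjects, 10% injected submaximal
records) and write their tables under `results/`; for example
`analysis/02_filter_and_summarize.py` reports the cohort's overall sex
difference (males ~18% higher VO2max/kg than females), and
`analysis/04_reference_equations.py` recovers the generating median
polynomial within ~3% and prints each trendline's R² and SEE.
Per-subject intermediates go under `scratch/`.

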
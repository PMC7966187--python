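# Methods

`vo2ref` builds age- and sex-specific reference values for maximum oxygen
uptake relative to body mass (VO2max/kg, ml·min⁻¹·kg⁻¹) measured by
cardiopulmonary exercise testing (CPET) on cycle ergometers, and validates
them against holdout data. This note records the models, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Maximal-effort screening

A CPET only measures VO2max if the subject actually reached maximal
exertion. A test is accepted as maximal when the respiratory exchange
ratio (RER = VCO2/VO2) is at least 1.0 **and** the maximum heart rate is
at least 85% of the age-predicted maximum from the Tanaka equation,
HRmax = 208 − 0.7 × age. Both comparisons are inclusive (a subject exactly
at a threshold passes). On top of the effort screen, the cohort exclusions
remove athletes, smokers, and subjects with BMI strictly above 30 kg·m⁻²
(BMI exactly 30 is kept). When a record fails several rules, the report
carries only the first in the fixed order athlete → smoker → BMI → RER →
HR, so exclusion reports are deterministic.

Whether a *validation* sample should be re-screened with the same criteria
is a protocol choice; `crossval_report` applies the screen by default and
exposes `apply_effort_filter=False`.

## The LMS (Box-Cox Cole-Green) model

Conditional on age t, VO2max/kg is modelled by three smooth curves: the
Box-Cox power L(t) (skewness), the median M(t), and the generalised
coefficient of variation S(t). The z-score of a measurement y is

    z = ((y/M)^L − 1) / (L·S)   if L ≠ 0,      z = ln(y/M) / S   if L = 0,

treated as standard normal; the centile at probability p is the inverse
transform at Φ⁻¹(p). The implementation switches to the logarithmic limit
for |L| < 1e−5, which keeps the transform continuous to ~1e−10 across the
switch. Centile z-values use the exact normal quantile (Φ⁻¹(0.97) =
1.880794), not the rounded ±1.88 convention of some chart traditions.

The BCCG log-density is

    log f(y) = (L−1)·ln(y/M) − ln(S·M) − z²/2 − ln(2π)/2,

i.e. the normal density of z times the Jacobian (y/M)^(L−1)/(S·M). The
requirement 1 + L·S·z > 0 formally truncates z; the truncation mass is
Φ(−1/(S·|L|)), which for S ≈ 0.2 is below 10⁻⁵ and is ignored in the
likelihood (and handled by rejection in the sampler). A quadrature test
confirms the density integrates to 1 within 1e−4 at (L, M, S) =
(0.5, 40, 0.15).

### Penalised-likelihood fitting

L, M and S are cubic B-splines (default: 8 equally spaced interior knots
over the observed age range) maximising

    Σᵢ log f(yᵢ) − λ_L ∫L″² − λ_M ∫M″² − λ_S ∫S″².

The penalty matrices are exact (3-point Gauss-Legendre per inter-knot
interval; the integrand is piecewise quartic). The optimiser is Fisher
scoring backfitting: cycles of M → S → L, each block taking one Newton-type
step using the analytic scores

    ∂ℓ/∂M = (z/S + L(z²−1))/M,   ∂ℓ/∂S = (z²−1)/S,
    ∂ℓ/∂L = ln(y/M) − z·∂z/∂L    (with its analytic L→0 limit),

and positive approximate expected-information weights
((1/S² + 2L²)/M², 2/S², 7S²/4). Each step is halved until the penalised
log-likelihood does not decrease, so the trace is monotone over accepted
iterations; convergence is declared when one full cycle improves it by
less than `tol` (default 1e−3, absolute). Non-convergence within
`max_iter` (default 50) is flagged on the result, never silent.

Smoothing can be given as explicit penalties or as target effective
degrees of freedom — EDF(λ) = tr[(BᵀWB + 2λP)⁻¹BᵀWB], solved by bisection
on log λ at initialisation. Defaults are EDF 3/5/3 for L/M/S: enough for
the median's curvature over a 6–65-year range while keeping L and S
nearly quadratic. These are configuration, not constants of the method.
An infinite penalty (or EDF ≤ 1) collapses the curve to a constant fitted
by scalar maximum likelihood — a deliberate numerical choice: the
cubic-spline penalty's null space is technically linear, but a constant is
what chart-makers mean by "maximally smoothed", it makes the limit exact,
and it matches the common practice of holding L fixed (`fix_l` pins it to
a chosen value, typically 1).

Initialisation follows robust, scale-free statistics: L ≡ 1, M from
running medians in age windows (quantile bins of ~100 records), S from
windowed SD/median, each projected onto the spline basis by ridge least
squares. Ages are used untransformed — the 6–65 range is narrow enough
that rescaling buys nothing. Fitting is deterministic given the data and
configuration; randomness exists only in simulation and sampling, always
behind explicit seeds.

Degenerate inputs: fewer than 50 records or fewer than 3 distinct ages are
rejected up front (a spline in age is meaningless there).

## Reference equations and the published-model comparison

Reference equations are polynomial trendlines in age fitted by ordinary
least squares to the P50 (median), P3 (lower limit of normal, LLN) and P97
(upper limit of normal, ULN) centile curves, with R² = 1 − SSres/SStot and
SEE = sqrt(SSres/(n − degree − 1)). The degree per band follows the
published equations (quadratic medians and female LLN; cubic male LLN/ULN
and female ULN). Constant input makes R² undefined (SStot = 0); the fit is
then flagged degenerate and collapsed to its degree-0 equivalent rather
than reporting a meaningless R².

The stored study equations (coefficients kept at their printed precision),
for ages 6–65:

* males — median −0.0049·age² + 0.0884·age + 48.263; LLN 0.0002·age³ −
  0.0227·age² + 0.5809·age + 31.909; ULN 0.00005·age³ − 0.0065·age² +
  0.0655·age + 64.801
* females — median −0.0021·age² − 0.1407·age + 43.066; LLN 0.0017·age² −
  0.3995·age + 35.084; ULN 0.0001·age³ − 0.0153·age² + 0.5674·age + 51.612

On a dense 6–65 grid LLN < median < ULN holds for both sexes (tested).
Classification against the limits is boundary-inclusive: a value exactly
at the LLN or ULN is "normal".

Legacy models are evaluated on the per-kilogram scale: Jones (males
55 − 0.44·age, females 43 − 0.36·age); Wasserman (males
weight·(50.72 − 0.372·age)/weight — weight cancels; females
(weight + 42.8)·(22.78 − 0.17·age)/weight); Cooper for children (boys
(52.8·weight − 303.4)/weight, girls (28.5·weight + 288.2)/weight). Where a
formula needs a body weight, the comparison uses the cohort's per-stratum
mean weight for the subject's sex and age band (ages past 60 use the
open-ended ≥60 band). The SHIP (Koch) equation is a named stub that raises
with a citation: only its table values, not its equation, are public.
Comparison-table cells are rounded half-up at one decimal — the tie rule
the published grid uses (48.05 → 48.1) — via `decimal`, not float
`round`. The study polynomials are tabulated to age 70 in the comparison
(matching the published grid) even though the cohort spans 6–65; direct
evaluation beyond 65 warns.

Percent-predicted, the clinical use of these equations, is
100 × measured / predicted.

## Cross-validation

Agreement on a holdout cohort is the paired t-test on per-subject
differences d = predicted − measured: mean, SD (n−1), t = mean/(SD/√n)
with n−1 degrees of freedom, two-sided p, α = 0.05. The sign convention —
positive mean difference means the equation over-predicts — is stated in
every report, because "difference in favour of the predicted value" is
ambiguous. Zero-variance differences give a degenerate comparison
(t and p reported as NaN with a flag) instead of an arbitrary p. When
training ids are supplied, holdout overlap is rejected.

## The synthetic cohort generator

No registry data are distributed, so every stage is exercised on seeded
synthetic cohorts shaped like the registry:

* n = 4612 with male fraction 3671/4612 (≈3.9:1), band counts proportional
  to the published strata (ages 6–65, dominated by the 20s–50s);
* heights and weights normal at the published per-stratum mean ± SD;
  weights are redrawn until BMI ≤ 30, mirroring the registry's
  pre-exclusion of obesity;
* VO2max/kg from the BCCG with M(age) = the study median polynomial per
  sex, S = 0.18 (males) and 0.23 (females) — back-computed from the
  published stratum SD/mean ratios — and L = 1 (the registry's true
  skewness is unknowable from summary tables, so the default is symmetric
  and the knob is exposed);
* HRmax normal around the Tanaka prediction with SD 10 bpm (the published
  stratum SDs are 8–12), truncated above the 85% threshold for maximal
  records; RER normal at the stratum mean with SD 0.08, truncated ≥ 1.0
  for maximal records;
* a configurable `submaximal_fraction` of records deliberately fails
  exactly one effort criterion (a `rer_fail_share` split between RER
  failures, drawn on 0.85–0.99, and heart-rate failures, drawn at 60–84.9%
  of predicted), giving the filter a known contamination rate to recover;
* a single `SeedSequence` spawns one substream per field.

What the generator does **not** emulate: centre and equipment effects,
the military-cohort fitness bias (beyond the `vo2_shift` mean-shift knob),
real skewness or age-dependence in S, and correlation between body size
and VO2max/kg within a stratum. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes — correct filtering,
centile estimation and equation extraction under a known generating
process — not that the published centiles would be reproduced from the
actual registry, whose raw data (and the chart-maker's smoothing settings)
are unavailable. For the same reason the published R²/SEE values and the
real cross-validation means are not assertion targets; the structural and
recovery properties that stand in for them are listed in the test suite
and the acceptance script.

## Problem sizes and tolerances

Simulation-based checks use n = 2000–5000 subjects — enough that binomial
(3√(p(1−p)/n)) and mean-recovery (≈0.2 ml·min⁻¹·kg⁻¹ SE) tolerances are
informative while the whole suite runs in seconds. Parameter-recovery
bounds: fitted M within 3% relative error on the interior ages 10–60 at
n = 2000 (edges are wider because spline variance grows there); constant-M
recovery within 2% under heavy smoothing; S within 15% (S is second-order
identifiable at these sample sizes). Transform round-trips are exact to
1e−10; the polynomial trend fit agrees with an independent
normal-equations solve to 1e−8 and is machine-exact on noiseless
polynomial input.
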
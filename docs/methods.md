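# Methods

## Scope

`lt2lab` implements a complete analysis pipeline for incremental cycling
step tests in young endurance athletes: detection of the second lactate
threshold (LT2), derivation of the three classical physiological
determinants of endurance performance, a model of power output at LT2
built from them, the maximal lactate accumulation rate from a 15-s
all-out sprint, and the cohort-level statistics used to judge the model
(agreement, stepwise regression, commonality analysis). A synthetic
cohort generator with known ground truth supports parameter-recovery
testing.

## Threshold detection (modified maximal deviation)

Per-stage end-of-stage blood lactate (bLa, mmol·L⁻¹) is regressed on
stage power with a third-order polynomial. The LT1 anchor is the lowest
power in the fit domain where the cubic's slope rises through
0.01 mmol·L⁻¹·W⁻¹ (configurable); if the slope already exceeds the
criterion at the first stage, the domain start is used. A chord is drawn
from that anchor (on the cubic) to the last **measured** point — the
highest power and bLa — and LT2 is the point of the cubic with maximal
perpendicular distance to the chord.

Numerics: stationary points of the deviation satisfy
`curve'(P) = chord slope`, a quadratic solved in closed form; all
interior real roots are compared by distance, ties resolved toward the
lower power. Because the perpendicular distance is the vertical
deviation times the constant factor `1/sqrt(1+m²)`, the maximizer is
identical for both definitions; the implementation is therefore
invariant to the choice and this is asserted against a 0.01-W grid
search in the tests. Degenerate inputs produce machine-readable
validity codes (`no-first-rise`, `no-deviation-max`, `order-violation`)
rather than numbers; cohort assembly uses them for exclusion
bookkeeping.

## Gas exchange and economy

- **V̇O2peak**: highest 30-s moving average of the per-second V̇O2
  trace; right-aligned full windows only, which makes the statistic
  deterministic at the series edges.
- **Exhaustion verification**: at least two of {RER ≥ 1.10,
  HR ≥ 0.95·(220 − age), bLa ≥ 8 mmol·L⁻¹, volitional exhaustion}.
  The 220 − age convention for the age-predicted maximum is the common
  default; missing heart rate simply removes that criterion.
  One-criterion tests are retained but flagged (strict mode excludes
  them).
- **Submaximal regression**: V̇O2 and V̇CO2 averaged over the last 60 s
  of every stage at or below the LT2 power (boundary stage included),
  then ordinary least squares on power. At least 80% of the expected
  per-second samples must be present in an averaging window.
- **Fractional utilization**: regression-predicted V̇O2 at the LT2
  power divided by V̇O2peak; carried as a fraction internally and a
  percentage only at I/O.
- **Oxygen cost (Cc) and gross efficiency (GE)** are evaluated *on the
  regression line* at three intensities — a fixed 3 W·kg⁻¹, the power
  where predicted V̇O2 reaches 75% V̇O2peak, and 90% of the LT2 power —
  because targets such as 90% LT2 generally fall between stages.
  Metabolic power for GE uses the non-protein stoichiometry
  EE [kcal·min⁻¹] = 0.550·V̇CO2 + 4.471·V̇O2 (L·min⁻¹), with
  1 kcal·min⁻¹ = 69.733 W. At fixed RER, GE·Cc is an exact constant;
  the tests assert this to 1e-9.

## The LT2 model and ċLamax

Power at LT2 is modeled as `frac_util · V̇O2peak / Cc`, one estimate per
Cc variant. With a zero-intercept submaximal regression and Cc evaluated
exactly at the LT2 power the model reproduces the criterion identically;
the positive physiological intercept makes Cc at 90% LT2 slightly
larger than Cc at LT2 itself, so the model underestimates by ~1-2% —
the tests pin both the magnitude (< 2%) and the direction.

ċLamax = (La_peak − La_rest) / (t_exerc − t_alac) with the full
programmed sprint duration (15 s) and an alactic interval of 3.5 s.
La_peak is the plain maximum of the minute-2..9 recovery samples; no
curve is fitted. A series that never exceeds rest yields 0 with a
`no-accumulation` flag rather than a negative rate.

## Agreement and association statistics

- **Bland–Altman**: fixed bias (mean difference, one-sample t-test
  against 0), random bias (mean ± 1.96·SD limits of agreement), and
  proportional bias (t-test of the OLS slope of differences on pairwise
  means). The relative variant divides each difference by the pairwise
  mean.
- **ICC(A,1)**: two-way model, single measurement, absolute agreement,
  from the n×2 ANOVA mean squares
  `(MSR − MSE) / (MSR + MSE + (2/n)(MSC − MSE))`, with the F-based 95%
  CI of the same definitional framework (Satterthwaite degrees of
  freedom). Interpretation bands 0.50 / 0.75 / 0.90.
- **Stepwise regression**: bidirectional search by AIC reduction from
  the intercept-only model; AIC convention `n·log(RSS/n) + 2k`, which
  differs from the likelihood form by an additive constant shared
  across models on the same data. The step trace is recorded;
  standardized betas come from a z-scored refit.
- **Commonality analysis**: all seven subset regressions of the three
  predictors; unique effects as the R² drop when a predictor leaves the
  full model, common effects by inclusion–exclusion. Components may be
  negative (suppression) and sum to the full-model R² to machine
  precision — asserted on every test input.
- Correlations (Pearson/Spearman) use the 0.30/0.50/0.70/0.90 bands;
  sex comparisons use the independent t-test or, on caller request
  (non-normal variables), the Wilcoxon rank-sum test. Normality routing
  is deliberately caller-supplied; no automatic pre-test is run by
  default to avoid double-testing.

## Synthetic cohort

The generator emulates the cohort structure the analysis assumes, with
sex-specific draws (means/SDs): relative V̇O2peak 61.3 ± 5.6 (m) /
53.4 ± 5.1 (f) mL·kg⁻¹·min⁻¹, body mass 60.1 ± 10.2 / 56.2 ± 6.1 kg,
Cc 13.3 (SD 0.9 / 1.0) mL·min⁻¹·W⁻¹, fractional utilization
0.832 / 0.807 (SD 0.04), ċLamax 0.48 ± 0.10 mmol·L⁻¹·s⁻¹, male share
61/83. Noise defaults: lactate SD 0.2 mmol·L⁻¹ (truncated at 0),
multiplicative V̇O2 CV 3%.

Key constructions and their rationale:

- **Protocol**: start at ~1.5 W·kg⁻¹ on the 20-W grid (kept in the
  40-120 W window), +20 W per 3-min stage until the first stage whose
  steady-state demand (`intercept + cc·P`, capped at V̇O2peak) exceeds
  V̇O2peak. The V̇O2 trace approaches each stage's steady state
  mono-exponentially (τ = 30 s); the first stage is entered from one
  standard increment below its demand, i.e. the warm-up is assumed to
  end at that level, so every on-transition has the same amplitude and
  the stage-mean undershoot is a pure intercept offset.
- **Lactate curve**: exponential `b0 + b1·e^{b2·P}` with b0 = 1.0,
  first-stage value b0 + 0.3, and peak-stage value drawn from
  8-12 mmol·L⁻¹ — deliberately outside the cubic family the fitter
  uses, so recovery tests are not circular, while guaranteeing a
  monotone convex rise with a well-defined first-rise point.
- **Operational ground truth**: `lt2_power_noiseless` is the modified
  maximal-deviation functional applied to the noise-free curve sampled
  every 1 W — the estimand of the method is exactly that functional,
  not an analytic landmark of the exponential. The geometry of a convex
  exponential under a cubic fit places this point at ~60-63% of the
  stage span, so the realized fractional utilization (recorded as
  `frac_util_op`, ≈0.80 ± 0.03) sits slightly below the drawn value,
  which therefore acts as a feasibility target rather than an exact
  constraint.
- RER rises linearly from 0.85 (first stage) to 1.12 (peak), providing
  plausible GE values and the RER exhaustion signal; heart rate tracks
  the noiseless V̇O2 fraction toward an age-predicted maximum.
- The sprint recovery series peaks at minute 5 at
  `la_rest + ċLamax·(15 − 3.5)` and decays 5% of the excess per minute,
  with the same lactate noise on every sample.
- Infeasible draws (fewer than five stages, threshold outside the
  stage range) are redrawn deterministically (bounded at 25 attempts);
  the per-athlete stream is seeded from `(cohort seed, index)` so any
  athlete regenerates identically regardless of cohort size.

What the generator does **not** emulate: V̇O2 slow-component kinetics,
lactate clearance dynamics, day-to-day biological variation, device
drift, or protocol deviations. Passing recovery tests therefore show
the pipeline is faithful to its own estimands under the stated noise
model — not that the model's accuracy on real athletes equals the
synthetic figures.

## Problem sizes and known limitations

Recovery tests use cohorts of 50 (noise-free) and 200 (default noise);
population-mean checks use 500; the cohort-structure property uses the
study-sized n = 83. These sizes give stable medians while keeping the
full suite fast.

Limitations worth knowing:

- The last-60-s stage means undershoot steady state by ≈2 mL·min⁻¹
  under τ = 30 s kinetics; this cancels in the regression slope but
  leaves a small intercept bias, so fractional utilization is recovered
  to ~1e-3 (median) rather than exactly, and relatively worse for very
  small athletes.
- Criterion LT2 and the 90%-LT2 Cc variant are not mathematically
  independent; the near-perfect cohort R² partly reflects that shared
  construction (true of the measured quantity as well).
- The commonality decomposition is implemented for exactly three
  predictors (the model's determinants); ċLamax enters only as an
  additional stepwise candidate in the sprint subgroup.
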
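# Methods

## Derived indices

All derived quantities are deterministic functions of the raw record.

- **BMI** = weight / height² (kg/m²), computed at admission and for the
  premorbid weight with the same (admission) height.
- **%IBW** — percent of ideal body weight, stored as a fraction. The ideal
  weight at a given height is the weight giving a BMI of 22 kg/m², so
  %IBW = BMI / 22 and the malnutrition criterion %IBW < 0.9 is identically
  BMI < 19.8. (The formula is sometimes printed with the height factor in
  the numerator, which is dimensionally inconsistent; this package uses the
  BMI/22 reading, which is the one consistent with the 19.8 equivalence.)
- **ΔBMI** = (admission BMI − premorbid BMI) / months since onset; negative
  values mean decline.
- **ΔALSFRS-R** = (48 − ALSFRS-R) / months since onset: the average monthly
  functional decline from the scale's ceiling.
- **RQ** = VCO₂/VO₂ (≈ 0.7 pure fat oxidation, ≈ 1.0 pure carbohydrate).
- **mREE** — abbreviated Weir equation without urinary nitrogen, gas rates
  in mL/min: `1.44 × (3.941·VO₂ + 1.106·VCO₂)` kcal/day.
- **pREE** — original (1919) Harris–Benedict coefficient sets, height
  converted to cm internally.
- **BMM index** = (BMI − 19.8) × (mREE/LSTM − 38).

### Boundary conventions

Fixed once, following the literal inequality wording of the definitions:
hypermetabolic iff mREE/LSTM **≥** 38 (closed); malnourished iff %IBW
**<** 0.9 (open); high BMM iff BMM **≥** 1; excess weight loss iff the
fractional loss from premorbid weight is **strictly** > 10 %; high
mREE/pREE iff **>** 1.1; low RQ iff **<** 0.85; high LDL iff **≥** 100
mg/dL; high body fat iff **>** 25 % (men) / 30 % (women).

### Missing data

Every derived value and flag is missing exactly when any required input is
missing; no imputation anywhere. Downstream analyses delete missing values
pairwise (per variable in comparison tables, listwise within each Cox
model) and always report the per-analysis n.

## Survival inference

Implemented natively (numpy), with lifelines as an independent oracle in
the test suite only.

- **Kaplan–Meier**: product-limit estimator; at tied times events are
  processed before censorings. Median survival is the smallest t with
  S(t) ≤ 0.5, undefined (NaN) if never reached.
- **Log-rank**: k-sample O−E chi-square over pooled event times with the
  hypergeometric covariance and the multi-event (N−d)/(N−1) tie factor;
  df = k − 1. A pseudo-inverse guards degenerate layouts.
- **Cox PH**: Newton–Raphson on the Efron partial likelihood (Breslow
  available), covariates centred internally, step-halving to keep the
  likelihood non-decreasing. Convergence when max |score| < 1e−9 or max
  coefficient change < 1e−9, cap 50 iterations. Non-convergence, constant
  covariates, rank deficiency and diverging coefficients (monotone
  likelihood / complete separation, |β| > 15) are flagged on the result and
  raised as `ConvergenceWarning`s — never silent. Wald standard errors from
  the inverse observed information; HR = exp(β), 95 % CI = exp(β ± 1.96·se),
  two-sided Wald p. Efron + Wald is the default of the clinical-statistics
  tool lineage this analysis style comes from; likelihood-ratio intervals
  are out of scope.
- **Time origins**: survival can be measured from symptom onset or from the
  admission; in the latter case endpoint-within-the-admission-month gives a
  zero duration, floored at 0.5 months so the subject enters the risk set
  (the curve then starts below 1). The floor is configurable.

## Group comparisons

Fisher exact (two-sided, minimum-likelihood convention: sum of
hypergeometric point probabilities ≤ the observed table's), Mann–Whitney U
(exact enumeration when both n ≤ 10 and tie-free, otherwise normal
approximation with tie and continuity corrections), Spearman rank
correlation (average ranks, t-approximation with n−2 df), and type-7
linear-interpolation quantiles for median [IQR]. These standard steps are
delegated to scipy/numpy behind the package's interface; the conventions
above were chosen because they reproduce the published contingency-table
p-values (0.027, 0.165, 0.063) to three decimals.

One published value does **not** recompute: the malnutrition-stratum PEG
comparison is printed as p = 0.035, but Fisher on the printed 7/9 vs 4/8
counts gives ≈ 0.335. The pipeline always reports the recomputed value;
the discrepancy is presumably a typo in the source table and is not
"corrected" for.

## Time-dependent ROC

Cumulative-case / dynamic-control ROC at a fixed horizon (default 24
months from onset): cases have the endpoint by the horizon, controls are
event-free beyond it. Censoring before the horizon is handled by the
classical Kaplan–Meier-weighted estimator — with S the all-sample KM curve
and S_c the KM curve within {marker > c},

    sens(c)     = (1 − S_c(t)) · P(M > c) / (1 − S(t))
    1 − spec(c) = S_c(t) · P(M > c) / S(t)

swept over all distinct observed marker values plus ±∞ (no midpoint
convention, matching the integer statement of the published cut-off). The
raw weighted estimates can be locally non-monotone under heavy censoring;
they are made monotone by a running maximum along the descending-cutoff
sweep and clipped to [0, 1]. Without censoring before the horizon the
estimator equals the plain empirical ROC exactly (tested). AUC is
trapezoidal; the Youden criterion maximises sens + spec − 1 with ties
broken toward the smaller cutoff; a preset criterion reports the curve
coordinates at a fixed threshold. An unweighted empirical variant is
available since the weighting used for the published curve is not
recoverable from the publication.

## Synthetic cohort generator

The patient-level data behind the published analysis are not deposited, so
the generator emulates the *stated world* of the publication's summary
tables and is the package's test bed. What it matches:

- marginals calibrated to the published medians/IQRs: age ~ N(70, 7.4)
  truncated at the enrolment floor of 49; admission BMI ~ N(21, 3);
  mREE/LSTM ~ N(36.8, 4.5) (centred so the generated median sits at the
  published 36.4 — the published distribution is right-skewed, so a
  symmetric marginal must be centred slightly below the mid-IQR);
  LSTM and body fat % sex-shifted normals; ALSFRS-R ~ N(39, 5.5) rounded;
  disease duration log-normal with median 15 months; blood and respiratory
  panels normal with published centres; 48 % female; bulbar onset 25 %.
- the latent 4-dimensional Gaussian copula over (BMI, LSTM, fat %,
  mREE/LSTM) carries the published correlation signs
  (mREE/LSTM: +0.36 with fat, −0.29 with BMI, −0.46 with LSTM; fat: +0.38
  with BMI, −0.54 with LSTM). The BMI–LSTM entry (+0.30) is not published;
  it is a plausibility choice (larger habitus, more lean mass) that keeps
  the matrix positive-definite.
- gas exchange is **back-solved** from each subject's target mREE/LSTM and
  a drawn RQ ~ N(0.83, 0.07) (≈ 60 % below 0.85), so profiling a generated
  record reproduces the generative BMM to machine precision (round-trip
  tested at 1e−9).
- survival: Weibull baseline (shape 1.3, scale 40 months ⇒ baseline median
  ≈ 30 months from onset) with log-hazard γ·BMM + δ·[excess weight loss].
  The continuous product term is the point: one coefficient γ > 0 makes
  hypermetabolism harmful above BMI 19.8 and protective below it. Default
  γ = 0.09 per BMM unit is a documented free choice (the publication gives
  no marker–hazard coefficient); δ = 1.12 ≈ ln 3, the published adjusted
  HR for excess weight loss. `gamma_for_group_hr(target)` solves
  γ = ln(target HR)/Δ(mean BMM between the BMM ≥ 1 and < 1 groups), the
  mean difference measured once on a large fixed-seed reference draw (a
  quadrature constant, not an experiment).
- times are sampled left-truncated at the admission time (subjects are
  alive when measured), with administrative censoring uniform over an
  admission-to-data-lock window (default up to 36 months); missingness is
  completely at random at the published per-panel rates (body composition
  2/48, blood panel 8/48, spirometry 2/48).

What it does **not** emulate: informative censoring, longitudinal
trajectories, measurement error in calorimetry/impedance, site or calendar
effects, and any real marginal shape beyond location/spread/skew-sign. A
green test on synthetic cohorts therefore establishes that the *pipeline*
recovers the structure it was told to plant — not that the published
effect sizes are reproduced; the published AUC/HR/p-values are
property-checked qualitatively (sign, detectability at n = 48), never
asserted numerically.

## Pipeline

`run_study` executes: enrolment exclusions (age < 49 strictly, prior
ventilation/PEG when those columns exist) → profiling → four-cell
stratification → comparison tables (metabolism within each nutritional
stratum; high- vs low-BMM) → KM/log-rank suite (metabolism overall and
within strata, excess weight loss, body fat, LDL, BMM group; from onset
and from admission) → time-dependent ROC on the BMM index (onset origin)
with Youden and preset-1 operating points → multivariable Cox from both
origins (high BMM, age, ALSFRS-R, excess weight loss, bulbar onset, %VC).
Empty or single-group strata are skipped with a logged warning. Identical
(cohort, config) inputs give identical results; the config hash in the run
metadata makes reruns checkable.

## Numerical choices

- Cox tolerances 1e−9 / 50 iterations; step-halving floor 2⁻³⁰.
- Linear predictors are max-shifted before exponentiation (shift-invariant
  partial likelihood) to avoid overflow.
- Log-rank uses a pseudo-inverse of the covariance, statistic floored at 0.
- Quantiles are type-7 everywhere.
- KM-weighted ROC estimates clipped to [0, 1] and monotonised as above.
- Thresholds validate positivity; the generator validates correlation
  positive-definiteness and missingness rates.

## Known limitations

Time-varying covariates, stratified/penalised Cox, proportionality
diagnostics, competing risks, AUC confidence intervals and incident/dynamic
ROC variants are out of scope. The Efron-vs-Breslow and Wald-CI choices are
assumptions about the original analysis platform, not facts recoverable
from the publication. The %IBW open/closed boundary conventions matter only
for subjects exactly on a threshold.
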
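# alsmet

Metabolic–nutritional prognostic analysis for early amyotrophic lateral
sclerosis (ALS) cohorts.

## The problem

In early ALS, hypermetabolism — a resting energy expenditure that is high
for the amount of lean tissue burning it — is usually treated as a poor
prognostic sign. But its meaning flips with nutritional state: among
normal-weight patients hypermetabolism is associated with shorter survival,
while among malnourished patients it can accompany *longer* survival
(plausibly reflecting a shift toward lipid fuel use). A single marker
captures this interaction by multiplying the two centred factors, the
**BMI–muscle-metabolism (BMM) index**:

```
BMM = (BMI − 19.8) × (mREE/LSTM − 38)
```

where BMI is the admission body-mass index (kg/m²), mREE the resting energy
expenditure measured by indirect calorimetry (Weir equation, kcal/day) and
LSTM the lean soft tissue mass from bioelectrical impedance (kg). The
reference values are the malnutrition line (BMI 19.8 = 90 % of the ideal
BMI of 22) and the hypermetabolism line (mREE/LSTM = 38 kcal/kg/day); the
index is large and positive exactly when both factors deviate in the same
direction, the configuration associated with poor prognosis. Patients with
BMM ≥ 1 form the high-risk group.

`alsmet` implements the full analysis pipeline around this index for
patient-level cohort tables: derived anthropometric/metabolic indices and
classification flags, group-comparison statistics (Fisher exact,
Mann–Whitney U, Spearman, median [IQR]), native Kaplan–Meier / log-rank /
Cox proportional-hazards inference (Efron ties, Newton–Raphson),
time-dependent ROC cut-off selection at a 24-month horizon, and a seeded
synthetic-cohort generator calibrated to the published summary statistics of
a 48-patient admission cohort — because the underlying patient data are not
publicly deposited, the synthetic cohorts are the test bed.

## Worked example

```python
import alsmet

cohort = alsmet.generate_cohort(alsmet.default_params(n=48), seed=1)
result = alsmet.run_study(cohort)

print(result.four_cell_counts["cells"])
print(round(result.roc["auc"], 3), result.roc["preset_at_bmm_cut"])
print(result.cox["onset"]["high_bmm"])
```

prints (seed 1):

```
{'normal_weight/normometabolic': 22, 'normal_weight/hypermetabolic': 6,
 'malnourished/normometabolic': 10, 'malnourished/hypermetabolic': 8}
0.727 {'cutoff': 1.0, 'sensitivity': 0.518..., 'specificity': 0.826..., 'criterion': 'preset'}
{'coef': 1.686..., 'se': 0.542..., 'HR': 5.397..., 'ci95_low': 1.867...,
 'ci95_high': 15.604..., 'p': 0.002...}
```

Reading: of the 46 subjects with complete body-composition data, the
four-cell nutrition × metabolism partition is 22/6/10/8; the BMM index
discriminates 24-month outcomes with a time-dependent AUC of 0.73 and, at
the preset cut-off of 1, sensitivity 0.52 / specificity 0.83; in the
multivariable Cox model from onset (adjusted for age, ALSFRS-R, bulbar
onset, excess weight loss and %VC) the high-BMM group carries an adjusted
hazard ratio of 5.4 (95 % CI 1.9–15.6). The same run shows the effect
reversal in the stratified log-rank tests: hypermetabolism is harmful
within the normal-weight stratum and protective within the malnourished
stratum (`result.logrank`).

Or from the shell:

```sh
alsmet simulate --seed 1 --n 48 --out cohort.csv
alsmet analyze --in cohort.csv --out results/
```

which writes the augmented cohort CSV, comparison tables, tidy KM curves,
ROC curve/summary, Cox fits and a run log under `results/`.

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch on a
seeded synthetic cohort of 48 — generation, profiling, stratified
comparisons, KM/log-rank suite, time-dependent ROC and both Cox models —
and writes the target JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The full study outputs land next to it under `results/study_outputs/`.
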
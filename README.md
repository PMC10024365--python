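# pednutriscreen

Malnutrition-risk screening for hospitalized children with congenital heart
disease (CHD), plus the statistical machinery to validate such a screening
tool against a reference standard.

Children with CHD are at high risk of disease-related malnutrition:
abnormal hemodynamics raise energy expenditure while feeding difficulties
cut intake. Ward nurses need a quick admission-time triage that flags which
children should go to a dietitian for full assessment. This package
implements such a triage score and everything needed to evaluate one:

* **LMS z-score engine** (`pednutriscreen.growth`) — anthropometric
  z-scores from growth-reference tables parameterized by the Box-Cox power
  *L*, median *M* and coefficient of variation *S*:
  `z = ((x/M)^L − 1)/(L·S)` (log form in the L → 0 limit), with linear
  interpolation of (L, M, S) between table rows and no extrapolation.
  Indicators: weight-for-age, height-for-age and weight-for-height for ages
  0–5 y; BMI-for-age for 5–18 y.
* **The screening score** (`pednutriscreen.screening`) — a 0–6 total of
  three subscores: disease risk (0–1, from a diagnosis registry), dietary
  intake over the previous month (0–2), and the anthropometric indicator z
  binned at −1, −2, −3 (0–3, with an overlay raising the subscore for
  WHO-overweight/obese children). Total ≥ 2 flags the child *at risk*.
* **Reference standards** (`pednutriscreen.criteria`) — the WHO z-score
  malnutrition rules (deficits at z < −2, severe beyond |z| = 3,
  overweight/obesity on WFA/BMI) and a configurable ASPEN-style
  single-time-point grading.
* **Diagnostic validation** (`pednutriscreen.diagnostics`) — confusion
  matrices, sensitivity/specificity/PPV/NPV, Youden's
  J = sens + spec − 1, Cohen's κ, ROC points at half-integer cut values,
  trapezoidal AUC, maximum-Youden cut-off selection, and the uncorrected
  Pearson χ² test for group contrasts.
* **Synthetic cohorts** (`pednutriscreen.cohort`) — an exhaustive integer
  search that rebuilds the validation cohort's score × WHO-status joint
  distribution from printed marginal counts, and an individual-level
  simulator that generates subject records by inverting the LMS transform
  from sampled z-scores.

## Worked example

`examples/validate_published_cohort.py` rebuilds the 1125-child validation
cohort from its printed marginals and re-derives every accuracy metric:

```
malnourished per score 0-4   : (5, 19, 119, 100, 29)
not malnourished per score   : (449, 301, 72, 27, 4)

cut-off  sens%  spec%  youden%
    0.5   98.2   52.6    50.8
    1.5   91.2   87.9    79.1
    2.5   47.4   96.4    43.8
    3.5   10.7   99.5    10.2
    4.5    0.0  100.0     0.0

selected cut-off (max Youden): 2
sensitivity 91.2%, specificity 87.9%, PPV 70.7%, NPV 96.9%
Cohen's kappa vs WHO standard: 0.72
trapezoidal AUC              : 0.924
```

Reading the output: of 272 WHO-malnourished children, 248 score ≥ 2
(sensitivity 91.2%), while 750 of 853 well-nourished children score ≤ 1
(specificity 87.9%); the Youden-optimal cut is score ≥ 2, κ = 0.720 marks
good agreement with the WHO standard, and the ROC area 0.924 summarizes
discrimination across all cut-offs. The other examples score a single
child, compute raw z-scores, and run the simulator end to end.

## Command line

A thin CLI wraps the same functions:

```bash
pednutriscreen score subjects.csv -o scored.csv        # batch screening
pednutriscreen validate scored.csv -o report.json      # accuracy metrics
pednutriscreen reconstruct -o cohort.csv --meta m.json # marginal rebuild
pednutriscreen simulate -o sim.csv --n 500 --seed 7    # synthetic records
```

Subject CSVs use lower_snake_case columns (`id, sex, age_months, weight_kg,
height_cm, diagnosis_code, dietary_intake, ...`); growth references are one
CSV per indicator and sex with `L, M, S` columns. Bundled defaults (a
synthetic reference set and the named-lesion diagnosis registry) are used
when no paths are given.

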
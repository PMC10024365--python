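# Methods

## The screening model

The tool scores a hospitalized child with congenital heart disease on three
elements at admission:

| element | values | source |
|---|---|---|
| disease risk | 0, 1 | registry tier of the primary CHD diagnosis |
| dietary intake | 0, 1, 2 | intake change over the previous month: none, reduced ≤ 50%, reduced > 50% |
| anthropometric indicator | 0, 1, 2, 3 | indicator z binned at −1, −2, −3, plus an overweight/obesity overlay |

The total (0–6) classifies the child as *at risk* when it reaches the
threshold, default 2. The anthropometric indicator is the weight-for-height
z for children under five years and the BMI-for-age z from five years on,
following the age applicability of the underlying growth references.

**Boundary convention.** The published bin inequalities are strict and
leave z = −1, −2 undefined. We assign boundaries to the more severe bin
(z = −2 scores 2; z = −3 scores 3 by the printed "≤"), consistent with the
WHO deficit convention "z < −2"; `score_anthropometric(boundary_to_severe=False)`
selects the milder reading. Note the deliberate asymmetry with the WHO
*classifier*, which uses strict `< −2` for deficit flags: a child at
exactly z = −2 receives anthropometric score 2 but is not WHO-malnourished.

**Overweight overlay.** The rubric awards 1 point for overweight and 2 for
obesity. "Overweight"/"obesity" are delegated to the WHO rules
(WFA z > 2 / > 3 under five; BMI z > 1 / > 2 above). The overlay is on by
default and can be disabled (`screen(overweight_overlay=False)`), which
reproduces a validation regime in which no overweight-only child is
flagged.

## LMS z-scores

A growth reference supplies (L, M, S) per axis value (age in months, or
length/height in cm, per sex and indicator). The z-score of measurement
x is

    z = ((x/M)^L − 1) / (L·S),   L ≠ 0
    z = ln(x/M) / S,             L = 0

Numerically the power branch is evaluated as `expm1(L·ln(x/M)) / (L·S)`,
which is exact in the L → 0 limit and avoids the catastrophic cancellation
of the naive form for |L| below ~1e−6; the explicit log branch is used for
|L| ≤ 1e−10. The inverse (used by the simulator) is
`M·exp(log1p(L·S·z)/L)`.

Between table rows, L, M and S are each linearly interpolated; queries
outside the table range raise an error rather than extrapolate. Ages are
fractional months (days/30.4375 via a helper). Implausible values
(|z| > 5) are reported as-is and flagged, not censored. The record's age is
taken as already corrected for gestational age.

## Reference standards

*WHO*: underweight ⇔ WFA (or BMI, over five) z < −2; growth retardation ⇔
HFA z < −2; low weight-for-height ⇔ WFH z < −2; overweight ⇔ WFA z > 2 or
BMI z > 1; obesity ⇔ WFA z > 3 or BMI z > 2; severe ⇔ any applicable
z < −3 or > 3. "Malnourished" is any deficit *or overweight* — an
unconventional but deliberate definition matching the validation design;
`classify_who(include_overweight=False)` gives the deficit-only variant.

*ASPEN-style*: a single-time-point grading of the wasting indicator
(WFH, else BMI) at configurable cut-points, defaulting to z ≤ −1 mild,
≤ −2 moderate, ≤ −3 severe, with "malnourished" at moderate or worse. The
exact indicator mix used in the original ASPEN comparison is not
recoverable, so these cut-points are configuration, not a claim.

## Diagnostic validation

Standard definitions throughout: sensitivity tp/(tp+fn), specificity
tn/(tn+fp), PPV, NPV, Youden J = sens + spec − 1, Cohen's
κ = (p_o − p_e)/(1 − p_e). Undefined ratios (0/0) are reported as missing,
never silently 0. ROC points are taken at half-integer cut values between
the observed integer scores ("positive ⇔ score ≥ t"), augmented with the
(0,0) and (1,1) endpoints; the AUC is the trapezoid over (FPR,
sensitivity) keeping the maximum sensitivity at tied FPR. The optimal
integer cut-off is the ceiling of the maximum-J threshold, ties broken
toward higher specificity then lower threshold (J is compared after
rounding to 12 decimals so float noise cannot hide an exact tie).

The Pearson χ² statistic is computed cell-by-cell from margin-derived
expected counts with **no continuity correction** — the uncorrected
statistic is what the printed group contrasts require — with a Yates flag
available for 2×2 tables. A zero expected cell raises an error naming the
cell. Printed-style rounding is half-away-from-zero: percentages to 1
decimal, κ/AUC/χ² to 3.

## Cohort reconstruction

The validation cohort's per-subject data are unavailable, but its printed
marginals over-determine the (score, WHO-status) joint distribution: the
per-score totals n_s, the malnourished total (272 of 1125), and the
per-cut-off sensitivity/specificity table. The reconstruction enumerates
malnourished-count vectors m_s ≤ n_s with Σm = 272 depth-first from the
highest score down; as soon as a tail m_{s..} is fixed, the sensitivity at
cut s − 0.5 (and the paired specificity) is determined and must round to
the printed value, so each printed row prunes exactly and the search
remains exhaustive over the constraint set. The result is asserted unique:
m = (5, 19, 119, 100, 29) against (449, 301, 72, 27, 4).

The printed per-score totals sum to 1126 against N = 1125. Every
single-score ±1 adjustment is tried; only lowering the score-3 total
128 → 127 survives the cut-off-table roundings (and preserves the printed
351/774 at-risk split), so that adjustment is applied and surfaced in the
fixture's metadata rather than silently. Scores 5–6 carry zero counts (the
maximum observed score was 4).

## The simulator

`simulate_cohort` draws sex (p(male) = 0.511), age (lognormal, median
23 months, clipped to 1–216), a diagnosis within a risk tier (tier-1
prevalence 0.168 = 189/1125), a dietary category ((0.9982, 0.0009, 0.0009)
— dietary risk was nearly absent in the validation cohort), a
height-for-age z ~ N(0, 1), and a target indicator z from
tier-stratified normals (defaults N(−0.4, 1.1) for tier 0 and N(−1.8, 1.2)
for tier 1, chosen so tier-1 children sit well below the growth median and
overall risk prevalence lands near one quarter to one third). Height
follows from the HFA reference at the sampled z; weight is obtained by
*inverting* the LMS transform of the target indicator (WFH under five,
BMI-for-age above), so rescreening a simulated record recovers the sampled
z exactly. These defaults are configuration describing a plausible cohort
of this kind, not estimates of the study population; only the
marginal-constrained reconstruction asserts fidelity to printed counts.

The bundled synthetic references use L = 1 and mutually consistent linear
medians — weight 4 + 0.25·age kg, height 50 + 0.5·age cm, hence
weight-for-height 0.5·len − 21 kg, with BMI-for-age tabulated from the
same medians at 3-month steps — so z-scores have closed forms and linear
interpolation is exact off-node. They emulate the *structure* of real
growth standards (monotone medians, realistic magnitudes), not their
shape: real references have age-varying L and S and nonlinear medians, so
passing tests demonstrate the correctness of the machinery, not
anthropometric realism. Users can drop WHO-format LMS tables (same
columns) into a reference directory for real use.

## Verification scale and determinism

The marginal reconstruction and all printed-table checks run in
milliseconds and are fully deterministic. Simulator checks use 80–400
subjects per run for unit tests and a 100-replicate × 200-subject pooled
parameter-recovery check, comparing the pooled at-risk prevalence to the
closed-form expectation (normal CDF over score bins, overlay off so the
closed form is exact) within three binomial standard errors of the pooled
n — a per-replicate 3-SE test would fail by chance in roughly a quarter of
100-replicate batches, so the pooled reading is the statistically
meaningful one. All random draws flow through `numpy.random.default_rng`
seeds; the same seed reproduces a cohort bit for bit.

## Known limitations

* The "other" diagnosis categories of the rubric are not enumerated
  anywhere; the bundled registry carries only the named lesions and is
  user-extensible.
* No recumbent-vs-standing 0.7 cm adjustment is applied when a
  weight-for-height table of the other axis kind is used as fallback.
* AUC confidence intervals (e.g. DeLong) are out of scope, as are
  Mann–Whitney/Kruskal–Wallis group comparisons and the discharge
  logistic regression — all would need per-subject data that was never
  published.
* The reconstruction recovers the joint (score, status) distribution only;
  it carries no age, diagnosis or length-of-stay structure.
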
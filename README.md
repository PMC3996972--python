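# popbenefit

Population-level risk/benefit analysis for biomarkers and risk factors used
in disease **early detection** versus **prevention**.

Association studies report odds ratios and prevalences; whether acting on a
marker actually helps a population depends on something those numbers hide:
every marker-guided intervention trades true-positive gains against
false-positive harms, scaled by how rare the disease is. `popbenefit`
implements the *ratio of population benefit* (RPB) family of indices that
makes this trade-off explicit, together with the supporting machinery —
exact reconstruction of the population 2×2 table from summary parameters,
population attributable risk (PAR%), decision-curve net benefit, an
equal-variance binormal model for continuous markers, stratified confounder
adjustment, and seeded synthetic cohorts with plug-in estimators. It is
aimed at epidemiologists and biomarker-translation researchers triaging
candidate markers before clinical deployment.

## The indices

For a binary marker, let `a, b, c, d` be the population fractions of
true-positive, false-positive, false-negative and true-negative subjects
(so disease prevalence `w = a + c`). With `f1` the life-value gained per
early-detected case and `f2` the life-value lost per falsely treated
non-case (one minus the QALY utility weight of the intervention):

```
RPB_detection  = (a·f1 − b·f2) / (a·f1 + b·f2 + c·f1 + d·f2)
RPB_prevention = (a·η·f1 − (a+b)·δ) / (same denominator)
```

where `η` is the efficacy of the preventive measure and `δ` the
adverse-effect loss per treated person. The denominator is the total
population stake `w·f1 + (1−w)·f2`; RPB < 0 / = 0 / > 0 flags the program
as detrimental / neutral / beneficial. Related quantities: `PAR% =
(r1 − r2)/r1 · 100` with `r1 = a+c`, `r2 = c/(c+d)`; net benefit
`NB = a − w_nb·b` (cost weight `w_nb = f2/f1` by default); absolute gain
`(a·f1 − b·f2) − h(a+b)` with per-treated cost `h`.

Because the 2×2 table is rarely published, `solve_two_by_two` recovers it
exactly from `(OR, marker prevalence, disease prevalence)` as the unique
admissible root of `(1−OR)·a² + [1+(OR−1)(p+w)]·a − OR·p·w = 0`.

Continuous markers use equal-variance Gaussian class-conditional densities
calibrated so the per-unit log-odds slope equals `ln OR` (mean shift
`σ²·ln OR`), with thresholds chosen by policy (fixed sensitivity, fixed
specificity, balanced, or explicit) and all indices evaluated from the
Gaussian tail areas (closed form) or by adaptive quadrature for arbitrary
densities and marker-dependent `η(x)`, `δ(x)`.

## Worked example

A marker with odds ratio 20 and 10 % carrier prevalence, for a disease of
1 % prevalence whose intervention costs 0.03 quality-adjusted life-value per
false positive:

```sh
$ popbenefit binary --or 20 --marker-prev 0.10 --disease-prev 0.01 --f1 1 --f2 0.03
{
  "sensitivity": 0.6752889591898742,
  "specificity": 0.9058109995877764,
  "par_percent": 63.92099546554157,
  "rpb": 0.09963416321550893,
  "nb": 0.003955476279655704,
  ...
}
```

Reading: used for classification this marker has 67.5 % sensitivity and
90.6 % specificity; as a causal exposure it accounts for 63.9 % of disease
burden; used to trigger the intervention it delivers about 10 % of the
maximum achievable population benefit (RPB 0.100 > 0, i.e. beneficial —
but only barely, because at 1 % prevalence false positives are 14× more
common than true positives). The same library call is
`scenario_report(BinaryMarkerSpec(20, .10), PopulationContext(.01),
BenefitWeights(1, .03))`.

The continuous analog, a binormal marker with per-unit OR 50 thresholded at
95 % specificity:

```sh
$ popbenefit continuous --or 50 --policy fixed_specificity --level 0.95 \
      --disease-prev 0.01 --f2 0.03
```

prints `"rpb": 0.119...` — positive, again driven by the high specificity.

Reference grids over OR × prevalence (binary) and threshold policy × OR
(continuous) are emitted by `popbenefit table1` and `popbenefit table2`;
`popbenefit simulate` / `popbenefit empirical` generate seeded synthetic
cohorts and re-estimate every index from individual-level data.

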
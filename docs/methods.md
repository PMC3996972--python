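# Methods

## Model and estimands

The package quantifies the population consequence of acting on a binary or
continuous marker. The primitive object is the joint distribution of marker
positivity and disease status, expressed as population fractions
`a, b, c, d` (true positive, false positive, false negative, true negative)
with `a+b+c+d = 1`. All indices are deterministic functionals of this
table (binary case) or of the class-conditional marker densities and a
threshold (continuous case):

- **Classification**: sensitivity `a/(a+c)`, specificity `d/(b+d)`.
- **Attributable risk**: `PAR% = (r1 − r2)/r1 · 100` with `r1 = a+c` the
  overall disease risk and `r2 = c/(c+d)` the risk among marker-negative
  subjects. (Some presentations label `r1` "prevalence" and `r2` the
  "false negative fraction"; the formulas implemented are the ones above —
  the false negative fraction proper is `1 − sensitivity`.)
- **Ratio of population benefit**: detection
  `(a f1 − b f2) / (f1(a+c) + f2(b+d))`; prevention
  `(a η f1 − (a+b) δ)` over the same denominator. The denominator is the
  marker-independent population stake `w f1 + (1−w) f2`, so RPB is bounded
  by `w f1 / (w f1 + (1−w) f2)`, attained only by a perfect marker.
- **Net benefit**: `a − w_nb · b` per unit population, the decision-curve
  quantity; **absolute gain** subtracts a per-treated cost `h(a+b)` from
  the RPB numerator.

Confounder adjustment is by stratification: the adjusted PAR% or RPB is the
case-proportion-weighted average of per-stratum values. Nothing beyond
weighted averaging (no Mantel–Haenszel or model-based adjustment) is
implemented.

### Assumptions

False negatives are assumed to fare exactly as they would without the
marker program (no extra penalty term), so only the `a` and `b` cells move
the numerator. `δ` is an absolute per-treated-person loss in the same
life-value units as `f1`, applied to every treated subject (`a` and `b`
alike). `f1` and `f2` are user inputs; estimating them (e.g. from QALY
utility studies) is out of scope.

## Reconstructing the 2×2 table

Given odds ratio `OR`, marker prevalence `p` and disease prevalence `w`,
cell `a` solves `(1−OR) a² + [1 + (OR−1)(p+w)] a − OR·p·w = 0` on
`[max(0, p+w−1), min(p, w)]`. Both roots are computed cancellation-free
(larger-magnitude branch first, companion root by Vieta's product); exactly
one is admissible and uniqueness is asserted. `OR = 1` bypasses the
quadratic as exact independence `a = p·w`. The solver is cross-checked in
tests against an independent Brent root-find of `a·d(a) = OR·b(a)·c(a)` and
recovers `OR`, `p`, `w` to 1e−9 over randomized parameters (OR 0.1–1000,
prevalences 0.001–0.99).

The rare-disease limit (`w → 0`) gives the closed forms
`sensitivity = pOR/(pOR + 1 − p)`, `specificity = 1 − p`,
`PAR% = 100·p(OR−1)/(p(OR−1)+1)`; the returned absolute risks `r1`, `r2`
are 0 (their limits). Agreement with the exact solution at `w = 1e−6` is
tested to 1e−4.

## Continuous markers

The default marker model is the equal-variance binormal pair
`N(μ_nd, σ²)` / `N(μ_d, σ²)` with `μ_nd = 0` and `σ = 0.5`. Under this
model the disease log-odds are linear in the marker with slope
`(μ_d − μ_nd)/σ²`, so calibration to a per-unit odds ratio fixes the mean
shift at `σ²·ln OR` — the unique equal-variance-normal model consistent
with a logistic risk model, and the one that reproduces the reference-grid
sensitivities. Positive calls are `x > c` (right tail).

Threshold policies: fixed sensitivity (`c = μ_d − σΦ⁻¹(level)`), fixed
specificity (`c = μ_nd + σΦ⁻¹(level)`), balanced (midpoint of the means
for equal σ), explicit. Exact Gaussian quantiles are used throughout, not
rounded critical values. A generic `DensityPair` contract accepts arbitrary
density callables; its thresholds are solved by Brent's method on the
relevant rate (|rate − target| < 1e−9) and its tail areas by adaptive
quadrature (absolute tolerance 1e−8, support truncated at μ ± 10σ for
Gaussian-like densities). Closed form vs quadrature agreement is tested at
1e−8; dichotomizing the continuous model at `c` and feeding the induced
fractions to the binary formulas reproduces the continuous results to
1e−12.

Marker-dependent prevention profiles `η(x)` (in [0, 1]) and `δ(x)` (≥ 0)
are integrated pointwise against each density; constant profiles reduce to
the closed forms and function-valued ones are cross-checked against Monte
Carlo sampling (3-SE agreement) in tests. Presets: constant, linear
(clipped), logistic.

ROC curves are generated over a descending threshold grid with (0,0)/(1,1)
endpoints and trapezoidal AUC; for the binormal model this agrees with the
closed form `Φ(Δμ/(σ√2))` to 1e−4 at the default 512 points.

## Reference grids

`generate_table1` crosses OR ∈ {1.5, 2, 4, 10, 20, 50} with marker
prevalence ∈ {0.1, 1, 10, 30, 70} % at 1 % disease prevalence;
`generate_table2` crosses the same ORs with three threshold policies
(sensitivity 95 %, specificity 95 %, balanced). Both carry RPB and NB
columns for three illustrative intervention loss weights, `f2` = 0.03
(esophageal adenocarcinoma), 0.06 (breast), 0.15 (ovarian), `f1 = 1`.
Disease prevalence is an explicit parameter everywhere in the public API;
1 % is only the grid default.

Rendering quotes the conventional print precision — rates and RPB/NB to 3
decimals (2 in the continuous grid), PAR% to 2 — using half-up rounding and
preserving the sign of values that round to zero (a raw −0.0001 prints as
`-0.000`, which distinguishes "slightly detrimental" from "slightly
beneficial" at print precision). Raw full-precision TSV is available
alongside (`--raw`).

## Synthetic cohorts

`simulate_binary_cohort` draws subjects from the multinomial over
`(a, b, c, d)` of the solved table — not conditional Bernoullis — so the
empirical odds ratio is unbiased for the generating OR by construction.
`simulate_continuous_cohort` draws Bernoulli(w) labels and class-conditional
Gaussians. Both are deterministic given a seed (numpy `default_rng`).

The generators emulate perfectly specified sampling: no measurement error,
no missingness, no covariate-dependent confounding beyond discrete strata,
and markers exactly Gaussian. Passing recovery tests therefore demonstrates
estimator consistency under the model, not robustness to real-data
violations of it. Plug-in estimators (count the empirical 2×2, apply the
binary formulas) are tested to recover sensitivity, specificity, PAR%, RPB
and NB within 3 delta-method standard errors across 20 seeded scenarios at
n = 1e5; test tolerances of 3 SE imply a ≈0.3 % per-assertion false-alarm
rate, made deterministic by fixed seeds.

## Numerical choices and edge cases

- Quadratic root selection tolerates 1e−12 boundary slack and clamps the
  root into the admissible interval; degenerate prevalences (0 or 1) are
  rejected up front with `InvalidInputError`.
- Zero margins raise `DivisionDegeneracyError` naming the margin; a zero
  RPB denominator (`f1 = f2 = 0` is rejected at construction; all-mass
  corner tables at evaluation) raises the same.
- Quadrature failures surface as `IntegrationFailureError` with the
  estimated error; unbracketed threshold roots as `SolverFailureError`.
- Reports carry raw unrounded values; rounding happens only at rendering.
- CLI exit codes: 2 for usage/validation errors, 1 for computation
  failures, 0 on success.

## Known limitations

- Point estimates only: no confidence intervals for OR, PAR% or RPB.
- Single-threshold net benefit, not full decision-curve analysis across
  threshold probabilities.
- Equal-variance Gaussian is the only parametric continuous model; other
  shapes enter via the `DensityPair` contract without special support for
  density estimation.
- The `h`-cost absolute-gain formulas are the only health-economics
  component; no discounting, time horizons or monetary conversion.
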
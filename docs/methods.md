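# Methods

## The estimation problem

Cystic index (CI) — the percent of kidney cross-section occupied by cysts —
is the outcome variable; it is measured by histology and therefore available
only post mortem (or post nephrectomy). The package derives a surrogate: an
affine formula in minimally invasive serum/urine biomarker levels, calibrated
on a 27-animal table from uninephrectomised male PCK rats (a *PKHD1*-mutant
ARPKD model, sacrificed at 13.5 weeks). The table ships with the package:
CI spans 0.45–34.49%, and eleven biomarkers plus kidney mass and kidney/body
mass ratio accompany it, with missing cells (`NA`) in several biomarker
columns. Urine biomarkers are 24-hour totals; the kidney/body mass ratio is a
derived column taken as printed (body mass itself is not part of the table).

## Missing data

Pairwise deletion throughout: a (biomarker, CI) pair enters an analysis iff
that biomarker's value is present; other analyses keep the animal. No
imputation anywhere. `paired_series` implements this and refuses to produce
series with fewer than 3 pairs. Consequently each univariate fit has its own
n (27 for BUN/SCr, 22 for urine IL-18, 12 for urine KIM-1, …).

## Trendline fitting and the correlation coefficient

Four families are fitted per variable, following spreadsheet curve-fit
conventions (the derivation this package re-implements was originally done
with spreadsheet trendlines):

- linear: OLS of CI on x;
- exponential: OLS of ln(CI) on x (requires CI > 0 throughout); r² is the
  fitting-space (log) coefficient of determination, as spreadsheets report;
- logarithmic: OLS of CI on ln(x) (requires x > 0 throughout);
- polynomial, fixed at degree 2: OLS of CI on (x, x²); r² in the original
  space. The degree is deliberately capped — higher degrees inflate r²
  mechanically and would subvert the screening gate.

r is defined from the trendline's r²: for the linear family it is the signed
Pearson correlation (sign of the slope); for the curved families the sign is
undefined and r = √r² ≥ 0. This keeps the invariant |r| = √r² across
families. Significance is always the two-tailed p of t = r√(n−2)/√(1−r²) on
n−2 df (`correlation_p_value`); |r| = 1 maps to p = 0. Family preconditions
that fail (a zero CI for the exponential family, a zero biomarker for the
logarithmic, n < 4 for the quadratic) skip the family and record why, rather
than erroring the screen.

Degenerate inputs: a constant predictor raises (no slope identifiable); a
constant response yields the linear fit (slope 0, r = 0, p = 1) and marks the
curved families inapplicable.

## The screening gate

A variable passes when

1. the best family's r (largest |r|; ties broken linear-first, then by the
   fixed order linear, logarithmic, exponential, polynomial2) satisfies
   **r ≥ r_min = 0.7** and **p < p_max = 0.05**;
2. the linear fit's |r| is within **linear_margin = 0.10** (absolute
   difference in r) of that best |r| — the *linear preference*: a slightly
   better curve is sacrificed for the linear equation, which is what the
   calculator can average;
3. the linear correlation is non-negative (the retained equations describe
   markers that rise with CI; an unsigned curved-family r cannot rescue a
   negatively sloped linear fit).

The retained equation is always the linear one. All three thresholds are
configuration (`GateConfig`), with the study's values as defaults.

Two readings of the gate were possible — apply r ≥ 0.7 to the linear r, or
to the best family's r. On the packaged table the linear r is 0.696 for BUN
and 0.662 for SCr, so the linear-r reading would reject both and contradict
the derivation this package reproduces; the best-family reading (BUN 0.791,
SCr 0.705, both quadratic) selects exactly {BUN, SCr, urine IL-18} among
fluid biomarkers. Likewise the ~10% linear-preference rule is implemented as
an absolute difference in r (BUN: 0.791 − 0.696 = 0.095 ≤ 0.10); the relative
reading (12.0%) would reject BUN. Both choices are the package's resolution
of ambiguity in the source derivation, selected because they reproduce it.

Biomarker eligibility for the calculator is a separate, configurable filter:
by default only serum/urine variables enter (`DEFAULT_ELIGIBLE_FLUIDS`).
Kidney mass and kidney/body mass ratio pass the gate (linear r = 0.73,
p < 0.01) but estimating CI from them would presuppose access to the organ.

## Signal averaging

Each retained equation CI ≈ aᵢxᵢ + bᵢ estimates the same quantity, so their
equal-weight mean improves fidelity the way averaging repeated noisy signals
does. The composite is exactly affine: coefficients aᵢ/k, intercept
mean(bᵢ), and the identity *composite prediction = mean of component
predictions* holds to floating-point for every panel (property-tested at
1e−12). Equal weights only — no precision weighting; k is not hard-coded to
3. Predictions outside [0, 100]% are returned as computed with an
`out_of_range` flag, never clamped.

## Rounding conventions

Coefficients are stored and combined at full precision; rounding happens only
at render time. Two display styles reproduce the printed forms of the source
derivation:

- `table` (per-equation): 0 decimals for |v| ≥ 1000, else 2 — giving
  0.95/−8.15, 53.62/−9.65 and 1368/11.27 for the three univariate equations;
- `formula` (composite): 0 decimals for |v| ≥ 100, 1 for |v| ≥ 10, else 2 —
  giving 0.32, 17.9, 456 and −2.18.

Averaging the full-precision slopes and rounding (0.95087/3 = 0.316956 →
0.32; 53.61842/3 = 17.8728 → 17.9; 1367.9487/3 = 455.983 → 456) agrees at
printed precision with averaging the already-rounded per-equation slopes
(0.95/3 → 0.32; 53.63/3 → 17.9; 1368/3 = 456 exactly); the package reports
the full-precision path.

## Known inconsistencies in the source table

The packaged table is the printed source data, kept verbatim; three internal
inconsistencies of the original publication surface rather than being
reconciled:

1. the published per-variable count for urine NGAL is 25 but the table holds
   24 values; for urine IL-18, 23 vs 22 (`count_discrepancies` flags both);
2. the published SCr equation (53.63·SCr − 9.66) is not reproducible from the
   printed values at the final digit: the n = 27 fit gives 53.61842 → 53.62
   and −9.654995 → −9.65. The published fit was evidently computed on
   unrounded source values (a ±0.005 rounding perturbation of the CI column
   moves the SCr slope by up to ~0.04). One test asserts the published
   rounding and therefore fails by design, documenting the gap; the composite
   formula is unaffected (17.873 → 17.9 either way). BUN and urine IL-18
   round exactly to their published equations.

## Synthetic data and parameter recovery

`generate` draws CI ~ Uniform(0.4, 35)% per animal, then for each *signal*
biomarker inverts a nominal relation CI = a·x + b and adds Gaussian noise on
the biomarker: x = (CI − b)/a + ε, ε ~ N(0, σ²), clipped at 0. *Null*
biomarkers are drawn independently of CI (lognormal/uniform/clipped-normal).
Each biomarker cell is then masked missing independently with `missing_rate`
(default 0.1, matching the real table's ≈11% missing cells); CI is never
masked. Identical configs (seed included) give bit-identical tables.

Noise on the predictor attenuates the fitted CI-on-x slope. With
Var(CI) = (hi−lo)²/12 and λ = Var(CI)/(Var(CI) + a²σ²):

    E[slope] → a·λ,  E[intercept] → mean(CI)·(1−λ) + λ·b,  population r = √λ.

`GroundTruth` carries both nominal and attenuation-corrected targets and the
recovery harness measures bias against the corrected ones. Two caveats are
measured, not ignored: (i) zero-clipping biases the closed form when levels
approach 0, so the per-replicate clipped fraction is reported; (ii) the
OLS slope is a ratio estimator, so at n = 27 its expectation exceeds the
asymptotic target by a finite-sample O(1/n) term of roughly +0.5% under the
default settings — below Monte-Carlo resolution at the 200-replicate scale
the tests run.

Defaults mimic the real table's marginals: a BUN-like marker (a = 0.95,
b = −8.15, σ = 4 mg/dL; levels ≈ 9–45), an SCr-like marker (a = 53.63,
b = −9.66, σ = 0.07 mg/dL; ≈ 0.19–0.83) and a urine-IL-18-like marker
(a = 1368, b = −4, σ = 0.0009 μg/24 h; ≈ 0.003–0.029). The IL-18 intercept
is −4 rather than the fitted +11.27 because inverting the fitted equation
would demand negative biomarker levels at low CI. The σ values keep levels
≥ ~2σ from zero (clipped fraction < 0.1%), making the attenuation targets
valid; they imply population r ≈ 0.93–0.99 — a well-behaved assay, cleaner
than the real study's r ≈ 0.66–0.78. Passing recovery tests therefore show
the pipeline recovers parameters *when its assumptions hold*; they do not
certify behaviour under the real data's heavier noise, skewed biomarker
distributions or correlated assay errors, which the generator does not model
(biomarkers are conditionally independent given CI, and there is no
time-course or disease-progression structure).

`recovery_experiment` reruns generate → screen → signal-average per
replicate (per-replicate seeds spawned from the config seed) and reports,
per signal biomarker, gate pass rate and slope/intercept bias and RMSE
against the corrected targets; per null biomarker, the false-positive pass
rate (essentially 0 at the r ≥ 0.7, n = 27 gate; < 5% asserted); and the
RMSE of the composite prediction against true CI. Simulation sizes in the
test suite (200 replicates at n = 27, 100 at n = 270) were chosen to resolve
these quantities while keeping the whole suite fast; RMSE shrinking by more
than 2× from n = 27 to n = 270 checks the ~1/√n consistency rate.

## Numerical choices

- OLS, Pearson r and the t-distribution come from scipy/numpy
  (`scipy.stats.linregress`, `numpy.polyfit`, `scipy.stats.t`); the fitting
  path is property-tested against closed-form centered normal equations at
  1e−10 relative tolerance.
- Family ties on |r| break linear-first, then by fixed family order, so
  screening is deterministic.
- Units are declared strings checked by name-match only; there is no
  dimensional-analysis engine. Panels must supply values in the declared
  units.
- The fixture loader verifies the packaged CSV cell-by-cell against a frozen
  in-source reference and names the first mismatching cell on corruption.

## Limitations

The calculator is calibrated on 27 animals of one strain, sex, age and
surgical model; coefficients carry no uncertainty intervals (none were part
of the source derivation), predictions are not clamped or recalibrated to
histology, and nothing here is clinical advice. The screening protocol
involves no multiple-testing correction and no joint (multivariate)
regression — it deliberately combines univariate fits only.
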
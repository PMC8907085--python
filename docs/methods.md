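# Methods

This note documents the statistical model, the synthetic-data
calibration, and the numerical and design choices behind `triscreen`.

## Risk model

**MoM normalization.** Screening markers are expressed as multiples of
the median (MoM). The package applies the median-curve convention of
the model family it re-implements: a base-10 quartic in gestational
age (days) and a reciprocal hyperbola in maternal weight (kg), with the
adjusted MoM defined as `MoM / (GA_med × Weight_med)`. Only the AFP-L2
gestational-age coefficients are published for this panel, so the other
markers default to the identity GA model; per-marker coefficient tables
can be supplied via the config. Two caveats are worth stating plainly:

* The published weight hyperbola (a = 0.8852, b = 9.465) evaluates to
  ≈ 0.70 at the control-group median weight of 50.1 kg, not ≈ 1 as a
  median-centred correction normally would; this looks like a units or
  transcription artefact in the source material. It is implemented
  exactly as printed. Because the correction is a smooth monotone
  function of weight it changes the scale of adjusted MoM but barely
  affects discrimination.
* The adjusted-MoM formula divides a MoM by the *product* of the two
  median terms rather than dividing the raw concentration by the GA
  median and then weight-correcting. Both conventions are implemented
  (`MoMTransformer(convention=...)`); the printed product form is the
  default.

**Maternal-age prior.** `risk_age = 0.0000697 +
exp(−18.4367 + 0.286·(age − 0.5))`, ages in years. These constants
differ from the classical published age-risk regressions; they are kept
as immutable defaults and all four parameters are configurable
(`AgeRiskParams`). The curve is strictly increasing; results are
clipped into (0, 1) with a logged warning if a pathological parameter
set pushes them outside.

**Likelihood ratio.** Each outcome class is a multivariate Gaussian
over the marker subset, fitted by moments (column means, unbiased
covariance) on log₁₀ adjusted MoM. The log transform is standard for
the multiplicative MoM scale and can be disabled
(`log_transform=False`) for sensitivity analysis. The likelihood ratio
is evaluated as a difference of log-densities and exponentiated last,
so no intermediate overflow occurs up to |log LR| ≈ 700. Combined risk
is `LR × risk_age`; the clinical "1 in N" value is its reciprocal.
Either ordering yields the same ROC curve.

**Covariance regularisation.** When a fitted class covariance is
numerically singular (smallest eigenvalue ≤ 1e-12), a diagonal ridge of
`1e-8 × trace/k` is added, escalated tenfold until positive definite,
with a floor of 1e-12 so that even an all-constant column yields a
proper (if arbitrary-width) density. The event is always logged; it
cannot occur on continuous data at the supported sample sizes.

**Model space.** All 2⁴ − 1 = 15 non-empty subsets of
{PAPP-A, free β-hCG, NT, AFP-L2}, enumerated by size then panel order;
model identifiers are '+'-joined marker names. Scoring is
resubstitution by default — densities fitted and evaluated on the same
cohort, matching the reference study design and therefore optimistic —
with stratified k-fold scoring available (`cv=k`).

## Synthetic cohorts

The generator emulates a 1:1 case-control design in which each
variable is known only through its median and 2.5th–97.5th percentile.

* **Markers** (MoM scale): two-piece (split) log-normal — Gaussian on
  the log scale with location `log(median)` and side-specific sigmas
  `(log median − log p2.5)/1.959964` and
  `(log p97.5 − log median)/1.959964`. All three printed numbers are
  matched exactly; the printed intervals are clearly asymmetric on the
  log scale, which a single log-normal cannot do (a pooled-sigma
  log-normal is available via `family="pooled"`). 1.959964 is
  Φ⁻¹(0.975).
* **Demographics** (age, weight, GA): the same two-piece mechanism on
  the natural scale, truncated to plausibility bounds (15–50 y,
  30–150 kg, 77–97 d) with truncation logged. Their printed intervals
  are near-symmetric, so natural-scale modelling is adequate.
* **Dependence:** a Gaussian copula on the log scale. The default is
  the identity — no inter-marker correlations are published for this
  panel, and the acceptance checks therefore run under independence —
  but any PSD correlation matrix can be supplied; rank correlations
  follow the copula identity ρ_S = (6/π)·arcsin(ρ/2).
* **Pseudo-raw mode** multiplies each MoM by the GA and weight median
  curves so the normalization stage can be exercised end-to-end; the
  round trip recovers the MoM values to < 1e-10 relative error.

What the generator deliberately does *not* emulate: the real cohort's
inter-marker correlation structure (unpublished), within-group
age–marker dependence, assay noise and measurement rounding, and the
exclusion-criteria filtering of the original design. Consequently,
passing tests demonstrate that the *methodology* reproduces the
published operating characteristics under the published marginal
distributions — not that it would produce identical numbers on the
original per-subject data. Cohort-specific quantities (bootstrap CIs,
per-cell diagnostic tables, IDI/NRI magnitudes) depend on the real
joint distribution and are treated as out of reach.

## Evaluation

* **Group comparison:** Mann-Whitney U with midrank tie correction and
  0.5 continuity correction (normal approximation); an exact
  permutation p-value is used for small untied samples.
* **AUC:** normalized midrank statistic (= trapezoidal area of the
  empirical ROC with half credit for ties). 95% CI by stratified
  percentile bootstrap, B = 2000, seeded, widened if needed to contain
  the point estimate; the Hanley–McNeil normal interval is available
  as an option. The p-value tests AUC = 0.5 with a normal
  approximation on the bootstrap SE. No DeLong paired test is provided:
  model pairs are compared via IDI/NRI instead.
* **Youden cutoff:** maximizes sensitivity + specificity − 1 over the
  observed thresholds; ties break toward the higher-specificity
  threshold. Subjects at the cutoff count as screen-positive. Cutoffs
  are reported both as risk scores and as "1 in N".
* **Diagnostic table:** DR, PPV, NPV, FPR, FNR, +LR, −LR from the 2×2
  table at the cutoff; prevalence is whatever the supplied cohort has
  (1:1 in the reference design). Empty-denominator ratios are NaN with
  a warning, mirroring the "–" convention of printed tables.
* **IDI:** difference in mean predicted-risk separation between models,
  p by the paired-difference normal approximation.
* **NRI:** continuous (category-free) by default — the reference
  model family publishes no risk categories, and the published NRI
  magnitudes (a few percent to ~26%) are inconsistent with a coarse
  two-category scheme at any obvious threshold, so the category-free
  variant is the only defensible default. Categorical NRI with
  user-supplied thresholds is provided. Both statistics operate on
  risk probabilities clipped to (0, 1); score pairs outside that range
  are jointly min-max rescaled with a warning.
* Two-sided tests throughout; report tables carry significance markers
  at 0.05 and 0.001.

## Problem sizes and tolerances

The validation suite uses: exact oracles (pair counting, permutation
enumeration, hand-worked 6-subject sets) at n ≤ 30; closed-form limits
(binormal AUC, density-crossing Youden cutoff) at 20 000 per group with
absolute tolerances 0.01 and 0.05; parameter recovery at n = 10⁴ (3 SE)
and percentile recovery at n = 10⁵ (3 Monte-Carlo SE, delta-method SE
for quantiles); stochastic reproduction of the published single-marker
AUCs and cutoff specificity as means over 50 replicate 40+40 cohorts
(tolerances ±0.06 AUC, ±0.05 on rates, ±5% on medians). These sizes
make the whole suite run in seconds while leaving the Monte-Carlo error
well inside each tolerance. Measured Mann-Whitney power at α = 0.001
for the calibrated AFP-L2 separation at 40+40 is ≈ 0.87.

## Known limitations

* Resubstitution AUCs at n = 80 are optimistic; the k-fold option is
  the honest alternative and gives systematically lower values.
* The two-piece distribution has a density kink at the median; it is a
  calibration device, not a mechanistic model of marker biology.
* The age prior and median-curve constants are taken as printed, not
  re-derived; the weight-correction scale issue above propagates into
  adjusted MoM values (but not into discrimination).
* With identity inter-marker correlation the multivariate models'
  *incremental* value over single markers is likely overstated relative
  to real data, where PAPP-A and free β-hCG are correlated.
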
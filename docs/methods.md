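# Methods

## Estimation model

All estimators share the identity LDL-C = non–HDL-C − VLDL-C with
VLDL-C approximated by TG/AF (all mg/dL). Friedewald is the special
case AF = 5 everywhere; the package treats it as a constant-AF lookup,
and `estimate_friedewald` is implemented so that it is bit-identical to
`estimate_martin_hopkins` with a constant-5 table (both compute
non–HDL-C first, then subtract TG/AF). Estimates are valid only for
TG < 400 mg/dL; `filter_eligible` excludes TG ≥ 400 before any
derivation or evaluation, and reports exclusion counts by reason
(missing fields, negative concentrations, high TG).

Negative estimates can occur at high TG with low non–HDL-C. They are
never clipped: they classify into the lowest guideline band and carry a
flag, since any clipping rule would be an invention with clinical
consequences.

Guideline bands (< 70, 70–99, 100–129, 130–159, 160–189, ≥ 190 mg/dL)
are applied to unrounded continuous values as half-open intervals
[lo, hi): exactly 100 mg/dL is "100–129". The labels "70–99" vs
"100–129" imply a partition at 100 for integer-reported values; for
fractional values a convention is needed, and half-open with no
pre-rounding is the one used consistently everywhere in the package
(TG strata and non–HDL-C cuts included).

## Ratio-table derivation

**Median tables.** Within each stratification cell, AF is the sample
median of the per-individual TG/VLDL-C ratios (even-sized cells: mean
of the two central order statistics). Individuals with VLDL-C ≤ 0 have
an undefined ratio and are excluded from median derivation (their count
is retained in diagnostics); they *are* included in optimal derivation,
whose objective needs only non–HDL-C, TG and the measured category.
The confidence interval for the median is distribution-free: the
symmetric-in-rank pair of order statistics (l-th, (n+1−l)-th), with l
the largest rank whose exact binomial coverage ∑_{k=l}^{n−l} C(n,k)/2ⁿ
reaches the nominal 95%. The achieved coverage (ACL) is reported
because it exceeds the nominal level except asymptotically; for n ≤ 5,
where no symmetric pair reaches 95%, the interval widens to the extreme
order statistics and the (smaller) achieved coverage is reported.
Derived AF values are stored rounded half-up to one decimal — the
resolution of the optimization grid and of published tables — and
serialized as decimal strings so file round-trips are exact.

**Optimal tables.** The grid is exactly {1.0, 1.1, …, 10.0} (91
points, generated as integers/10 to avoid float accumulation). Per
cell, AF is the grid value maximizing the count of members whose
estimated band equals their measured band. Ties break deterministically
to the lowest grid value and are recorded in the cell metadata (the
concordance curve is piecewise constant, so exact ties occur in small
cells). Because the estimate is strictly increasing in AF when TG > 0,
the under-classification count is non-increasing and the
over-classification count non-decreasing along the grid; this monotone
trade-off is asserted by property tests, and implies the concordance
curve is unimodal-ish but not necessarily concave — hence the
exhaustive scan rather than any local search.

Derivation uses whatever cohort is passed in; splitting
derivation/validation populations is the caller's responsibility (the
analysis scripts derive on the combined cohort and validate on the
survey-like one).

## Evaluation suite

- Concordance rates carry exact Clopper–Pearson 95% CIs (beta
  quantiles, via statsmodels); grouping by TG stratum or by
  estimated-value category, the printed-table convention of classifying
  by the estimate first.
- Paired comparisons of concordance use the exact two-sided McNemar
  test: p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½), from the
  two discordant counts. Tail doubling (not mid-p) is the convention:
  it reproduces the published worked examples (0.311 from (14, 21);
  0.021 from (1, 9)).
- Reclassification blocks individuals by the reference method's
  category and cross-tabulates correct/incorrect classification by
  reference and alternative against the measurement, with per-block
  exact McNemar p from the two discordant cells, plus upward/downward
  move counts. Percentages are within-block, rounded half-away-from-zero
  to one decimal, matching printed-table style; tests compare at the
  rounded convention.
- Bland–Altman agreement reports mean bias and limits of agreement
  bias ± 1.96·SD using the literal 1.96 (not a t-quantile), SD with
  ddof = 1.
- Fit metrics treat the measurement as truth: R² = 1 − SSE/SST (a
  prediction R², negative when an estimator is worse than the
  measured mean), MRE is the *signed* mean relative error in percent
  (rows with measured value 0 are excluded and counted), MAE in mg/dL,
  MSE in mg/dL². Signed MRE is chosen because published metric tables
  pair sub-percent MRE with multi-mg/dL MAE, which is only consistent
  with signed errors cancelling.

## Synthetic cohorts

The generator emulates the joint lipid structure the analysis needs,
not any real individual-level data:

- TG, non–HDL-C and HDL-C have log-normal marginals parameterized by
  median and IQR (right-skewed survey distributions are reported that
  way). The family matches the median and the IQR *ratio* exactly; the
  individual quartiles follow to within ~1%.
- TG and non–HDL-C are coupled by a Gaussian copula with Spearman rank
  dependence 0.35 by default — a deliberate, documented guess chosen to
  keep all 12 combined-scheme cells populated; survey-specific joint
  dependence is unknown here.
- Each individual's true TG/VLDL-C ratio is log-linear,
  r = 3.93 + 1.9·ln TG − 1.6·ln non–HDL-C, times multiplicative
  log-normal noise (σ = 0.20 by default), clamped to (1, 12). The
  coefficients are calibrated so that derived 6-cell medians rise
  strictly with TG and, within a TG stratum, the elevated non–HDL-C
  half has the lower median — the published qualitative pattern — while
  staying near published ratio levels (generated 6-cell medians ≈
  3.3–6.6). The noise level is set from the published 6-cell CI widths:
  a CI half-width of ~0.065 at n ≈ 3,100 implies a within-stratum
  log-scale spread of ~0.27, part of which the surface explains,
  leaving ~0.2 residual.
- VLDL-C = TG/r and measured LDL-C = non–HDL-C − VLDL-C, so derived
  quantities reconstruct the inputs exactly; TC = non–HDL-C + HDL-C.
  Rows with non-positive LDL-C are rejection-resampled (not clamped,
  preserving the marginals) with a hard cap of 100·n total draws.
- Presets: `population1` (TG median 102, IQR 69–150, the validation
  population), `population2` (TG truncated to [200, 400); its
  pre-truncation log-normal constants μ = 4.1012, σ = 0.7581 were
  solved by least squares so the *truncated* quartiles match the
  published 219/247/291), and `combined`, the 11,930 : 6,392 fixed-
  weight mixture used for derivation. Generation is bit-reproducible
  for a fixed seed (component streams are spawned from the seed).

For parameter-recovery experiments the surface can be replaced by a
cell-wise constant true ratio table (`ratio_table` in the config), and
`set_ratio_noise` adjusts the noise through mixture components.
Recovery runs use σ = 0.1 ("moderate" noise, the controlled-experiment
condition): there the grid-search optimum recovers a cell-constant
truth within 0.2 in every stratum holding ≥ 2,000 members (n = 20,000
cohorts). At the realism default σ = 0.20 the argmax sampling spread in
a ~2,000-member cell is itself of order 0.2–0.3, so recovery at that
tolerance is not guaranteed — a property of the estimator, documented
rather than hidden.

**What passing tests do and do not show.** The synthetic cohorts have
no assay error, no age/sex structure, no fasting-status artifacts, and
a parametric ratio surface; tests passing on them validate the
*algorithms* (derivation, estimation, inference arithmetic) and the
generator's calibration targets, not the clinical accuracy of any
ratio table on real populations. Published headline concordances from
survey data are not reproducible from synthetic cohorts and are not
asserted anywhere; published ratio-table *values* ship as data
fixtures and are checked as such.

## Numerical choices

- Interval logic is half-open everywhere; TG outside (0, 400) raises
  rather than clamps.
- Percentages print at one decimal, rounded half-away-from-zero
  (`round_half_up`), the printed-table convention; internal rates stay
  full precision.
- The 28-cell builtin scheme and the 12-cell TG-only scheme ship with
  synthetic boundaries (guideline-aligned non–HDL-C cuts; halved TG
  bands): the corresponding published boundary tables are supplementary
  material not included here, and the file format accepts user-supplied
  replacements.
- Problem sizes in tests and analysis scripts (cohorts of 18,322 /
  11,930 / 20,000; 10⁵-panel equivalence checks; 2,000-draw coverage
  simulations) are chosen to make Monte-Carlo assertions stable at the
  stated tolerances while keeping the whole suite fast.

## Known limitations

- Single-unit (mg/dL) support; no mmol/L conversion.
- No survey weighting, assay-error simulation, or alternative published
  regression-form equations (the fixed/lookup interfaces accommodate
  adding them as tables or callables).
- The 180-cell published median matrix is not shipped (not printed in
  the source material); users can supply it via the ratio-table format.
- Optimal-ratio derivation is in-sample by design; no cross-validation
  or smoothing across neighboring cells is attempted.
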
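# Methods

## Data-generating model

One simulated experiment is a 2×2 factorial: sex (reference / variable) ×
treatment (control / treated). Responses are Gaussian within each cell,

    y_i ~ Normal( μ(s_i, t_i), σ²_{s_i} ),

with cell means built additively from a baseline `mu0`, a sex main effect
`beta_sex`, a treatment main effect `beta_trt` and an optional
sex-by-treatment interaction `beta_int`. All three effects are expressed in
units of the reference sex's SD (`sigma_ref`), i.e. as standardised mean
differences *d*. Standardising against the *reference* SD — not a pooled SD
— is deliberate: it holds the scientific effect fixed while the
heteroscedasticity level varies, which is what makes required-sample-size
comparisons across scenarios meaningful. The interaction is conventionally a
magnitude modifier of the sex effect; a `beta_int` that flips the direction
of the sex effect in the treated group triggers a warning, not an error.

### Heteroscedasticity scenarios

The SD ratio `r = σ_variable / σ_reference ≥ 1` takes canonical values 1.00,
1.44 ("small") and 1.73 ("large"), exposed as presets. Two constraint modes
resolve `(σ_ref, σ_var)` from `(sigma_ref, r)`:

* **REFERENCE_FIXED** — `(sigma_ref, r·sigma_ref)`. Raising `r` raises the
  design's average residual variance by `(1 + r²)/2`; for r = 1.73 that
  factor is ≈ 2.0, which is exactly the required-sample-size doubling the
  simulations reproduce.
* **MEAN_VARIANCE_FIXED** — SDs `(σ_lo, r·σ_lo)` with
  `σ_lo = sigma_ref·√(2/(1+r²))`, so the average of the two variances equals
  `sigma_ref²` to machine precision. This isolates variance *imbalance* from
  overall noise level.

A variance-ratio constructor (`scenario_from_variance_ratio`) is provided
because heteroscedasticity is quoted in the literature sometimes on the SD
scale and sometimes on the variance scale; the two differ materially
(doubling a variance raises the SD by only 41%). The SD-ratio values are the
canonical parameterisation here because they are what drives power.

### Allocation and rounding

Per-cell sample sizes are `allocation · n_total` rounded by the
largest-remainder (Hamilton) method: floor everything, then hand the missing
units to the cells with the largest fractional parts, ties broken by cell
order (reference-control, reference-treated, variable-control,
variable-treated). Counts always sum to `n_total`; any resolved cell below
two observations is an error, since per-cell variances would be
inestimable.

### Seeding

A single integer seed is expanded through numpy `SeedSequence` spawning: one
child stream per design cell (and, in Monte Carlo loops, one grandchild set
per replicate). Two consequences: (1) datasets are bit-reproducible given
(scenario, n_total, seed); (2) a cell's draws do not depend on the other
cells' sizes, so datasets of different `n_total` from the same seed share
each cell's leading observations. The second property is what makes common
random numbers effective in the sample-size search.

## Mean–variance demonstration generators

**Constant-CV log-normal groups.** For target mean `m` and coefficient of
variation `cv`, the log-scale parameters are exact moment matches:
`σ_log² = ln(1 + cv²)`, `μ_log = ln m − σ_log²/2`, giving a distribution
with mean exactly `m` and SD exactly `cv·m`. Because `σ_log` is shared
across groups, the population SD is proportional to the mean and the
population log–log mean–SD correlation is 1; sampled groups show
correlations above 0.9 at realistic sizes (30 groups, n = 30). The naive
`exp(Normal(ln m, cv))` parameterisation is *not* used — its mean is biased
upward by `exp(cv²/2)`.

**Logistic ceiling mapping.** A latent trait `x ~ Normal(mean, sd)` is
mapped through `y = L/(1 + exp(−k(x − x0)))`. Near the midpoint the
delta-method SD is `L·k·sd/4`; as the latent mean moves toward the tails the
response SD shrinks (ceiling/floor compression), producing a *negative*
mean–SD association — the diagnostic signature distinguishing bounded-scale
artefacts from Taylor's-law scaling.

These generators emulate the mean–variance mechanisms only. They do not
reproduce other features of real grouped data — unequal group sizes,
between-study heterogeneity, measurement error, outliers — so passing tests
demonstrate the statistical machinery, not robustness to those features.

## Estimators

The fitted model is `response ~ sex + treatment (+ sex:treatment)` with
treatment-dummy coding (reference sex, control treatment as baselines). The
coding convention matters for interpreting per-term power and is fixed
throughout.

* **Classical OLS** — covariance `s²(XᵀX)⁻¹`, `s² = Σe²/(n−k)`.
* **Sandwich (HC0–HC3)** — `(XᵀX)⁻¹ Xᵀ diag(w) X (XᵀX)⁻¹` with
  `w = e²` (HC0), `e²·n/(n−k)` (HC1), `e²/(1−h)` (HC2), `e²/(1−h)²` (HC3),
  where `h` are the leverages. HC3 is the default flavor for the
  "recommended analysis" path on small-sample grounds; all four are exposed.
* **FGLS** — iteratively reweighted least squares with one variance per
  sex. Each iteration solves the weighted normal equations with weights
  `1/σ̂_sex²`, then re-estimates each `σ̂_sex²` as that sex's residual sum of
  squares divided by `n_sex − k·(n_sex/n)` — the sex's observation count
  less its proportional share of the model degrees of freedom. Iteration
  stops when the largest coefficient change drops below `tol = 1e-8`
  (typically 4–8 iterations); non-convergence after `max_iter = 50` raises
  an error carrying the last iterate. A within-sex residual variance at or
  below 1e-12 of the overall residual mean square is treated as degenerate.
  The reported covariance is the model-based `(XᵀWX)⁻¹`.

All term tests use a Student-t reference with `df = n − k`, including the
sandwich and FGLS paths. For the sandwich this is conservative relative to a
normal reference at small n; for FGLS a Satterthwaite-type df would be more
accurate at small per-sex n and is deliberately omitted as out of scope
(see Limitations).

## Monte Carlo design

**Rejection rates.** `rejection_rate` simulates R experiments, fits the
chosen model, and counts two-sided rejections at α (default 0.05, no
multiplicity correction across terms). Defaults: R = 2,000 for power curves,
10,000 for Type I error studies — sized so the binomial MC SE is ≈ 0.9
points at 80% power and ≈ 0.2 points at the 5% null. Replicate-level fit
failures propagate by default; a drop-and-count policy is available.

**Analytic oracle.** For balanced allocation without interaction, the
treatment (or sex) main effect is a difference of two half-sample means with
variance `(σ_ref² + σ_var²)/(2·n_cell)`; power follows from the noncentral t
with `df = n_total − 3`. It is exact for known variances and a close
approximation to the estimated-variance test; the suite verifies agreement
with the simulation within Monte Carlo error on an (n, d) lattice.

**Sample-size search.** `required_n` starts from the analytic crossing point
where the oracle applies (otherwise n = 32), brackets the target power
geometrically (factor 1.5 down / 2 up), then bisects over integers. All
candidates are evaluated with the *same* seed: by the per-cell substream
design the candidate datasets are nested, so the empirical power curve is
monotone enough for bisection. The returned `n_total` is the smallest whose
common-random-number power estimate reaches the target; because that
estimate is selected, the honest performance check is a validation run at
the returned n with an independent seed, which the acceptance suite
performs (R = 5,000).

**Type I error demonstration.** Balanced pooled tests are nearly calibrated
even under heteroscedasticity, so the inflation demonstration undersamples
the more-variable sex: cells 20/20 (reference) and 10/10 (variable) at
n_total = 60, SD ratio 1.73. The classical sex-term test then rejects a true
null at ≈ 9–10%; HC3 restores ≈ 5% in the same design.

## Taylor diagnostics

Per-group sample moments (SD with the n−1 denominator; CV reported only for
positive means) feed a least-squares line of log SD on log mean and its
Pearson correlation. Base-10 logs are the plotting convention and the
default; the correlation is base-invariant, the slope is not. Groups with
non-positive mean or zero SD are excluded and reported, never silently
dropped; at least three usable groups are required. Fits are unweighted by
default with an optional sample-size weighting, and can be stratified (e.g.
per sex).

## Numerical and design choices

* Rejection uses the strict comparison |t| > t_crit (equivalently p < α);
  the event p = α has probability zero for continuous responses.
* `analytic_power` accepts non-integer `n_total`; the search uses the
  continuous curve for its initial guess only.
* Cell-count rounding ties break by fixed cell order, so counts are
  deterministic, not platform-dependent.
* Grid runs derive one integer seed per grid cell from the master seed;
  rerunning a grid reproduces every row, which is also the resumption
  mechanism. Completed rows are appended to the output CSV before any
  failure propagates.
* CSV interchange uses F/M sex labels; which label is the more-variable sex
  is scenario metadata (`variable_sex`, default M). Internally the levels
  are `reference`/`variable` so the statistics never depend on the label.

## Test problem sizes

The suite exercises the claims at sizes chosen to keep Monte Carlo error
well inside the asserted tolerances: R = 2,000 for power comparisons and
sample-size searches, R = 10,000 for null-calibration checks, n = 400,000
for generator-consistency checks, n = 100,000 for FGLS variance-ratio
recovery (±0.02), and 5,000 replicates for the p-value uniformity
(Kolmogorov–Smirnov) check.

## Limitations

* FGLS with estimated weights and a model-based t reference is slightly
  anti-conservative at small per-sex n (≈ 6% empirical size at n_total = 64
  under the null); it calibrates by n_total ≈ 200. A Satterthwaite-type df
  correction would repair the small-n behaviour and is a natural extension.
* At most two variance groups (the sexes); no location-scale or mixed
  models, no Bayesian estimation.
* Allocation is a user parameter; the package does not optimise unbalanced
  allocations, although unbalanced designs can be simulated and analysed.
* The analytic oracle covers balanced, no-interaction designs only; power
  for other configurations is simulation-only.
* No meta-analytic machinery (group weighting by study, lnCVR/lnVR effect
  sizes) behind the Taylor diagnostics.
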
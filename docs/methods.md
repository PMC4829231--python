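# Methods

## Model

`smeedfit` implements the modified Smeed relation between a country's
road-traffic mortality and its motorization level:

    D/P = a · (N/P) · e^(−b·N/P)

with `D` annual road-traffic deaths, `N` registered motor vehicles and `P`
population.  Throughout the package `D/P` is measured in **deaths per
100,000 persons** and `N/P` in **motor vehicles per person**.  This pair of
scales is load-bearing: the multiplicative parameter `a` is expressed in
deaths per 100,000 per (vehicle/person), and the derived quantities
`PMM = a/(e·b)` and `1/b` are only comparable across countries on these
units.  All fitting uses them; they are fixed, not configurable.

The log transform `Y = ln(D/P) − ln(N/P)`, `X = N/P` maps the curve onto
the simple linear model `Y = β₀ + β₁X + ε` with `β₀ = ln(a)`, `β₁ = −b`,
estimated by ordinary least squares.  The model assumes independent,
homoscedastic Gaussian errors on the log scale — i.e. multiplicative
(lognormal) noise on mortality — and treats the annual observations as
exchangeable points: no autocorrelation structure is modelled, which is why
panels with gap years are acceptable inputs.

For `b > 0` the curve is unimodal: the derivative `a·e^(−bx)(1 − bx)` is
positive below `x = 1/b`, zero at it and negative above, so the global
maximum is `PMM = a/(e·b)` at motorization `1/b`.  A fit with `b ≤ 0`
describes a monotone mortality–motorization relation; the peak quantities
are then undefined and the reporting layer marks them as such (NaN / no
label) rather than failing, since a monotone regime is a legitimate outcome
for a country still early in motorization.

## Data conventions

* Input panels are comma-separated UTF-8 CSV, one row per (country, year),
  columns `country, year, deaths, vehicles, population[, definition]`.
  Rows with a missing count are dropped and logged; duplicate
  (country, year) pairs are an error.
* Deaths recorded under a 7-day post-crash definition are multiplied by
  1.08 to obtain 30-day equivalents.  The product is kept at full
  precision: the factor is a statistical correction, not a recount, so
  fractional death counts are intentional.  The conversion is idempotent
  and is also applied defensively inside `transform_series`, so a
  mixed-definition panel cannot silently bias a fit.
* Records with zero deaths or zero vehicles fall outside the domain of the
  log transform; they are excluded from the regression (and logged), not
  treated as errors.  A series must retain at least 3 usable points to be
  fitted; the container type itself accepts shorter runs so that I/O-level
  filtering can be reported faithfully before fitting fails.

## Estimation and diagnostics

OLS estimation, R², the F test on (1, n−2) degrees of freedom and the
influence measures are computed with statsmodels.  The test suite verifies
the fit against hand-written normal equations (tolerance 1e−10) and the
externally studentized residuals against literal leave-one-out refits, so
the library is cross-checked, not trusted blindly.

Outlier rule: an observation is flagged when |externally studentized
residual| > 3.0 **or** Cook's distance > 1.0.  Both inequalities are
strict; a value exactly at a threshold is not flagged.  Design choices
behind this rule:

* **Externally** studentized residuals (leave-one-out variance) are used
  for flagging, since the |t| > 3 convention refers to that variant; the
  internally studentized value is computed and exposed alongside for
  sensitivity analysis.
* Exclusion is **single-pass** by default — fit, diagnose, remove all
  flagged points, refit once.  An iterative mode (`iterative=True`)
  repeats the cycle until nothing is flagged, but is off by default: the
  single pass is the transparent, order-independent procedure.
* If an exclusion would leave fewer than 3 points the fit is returned
  without exclusion, with a warning, rather than failing.
* Cook's distance uses the standard form eᵢ²hᵢ / (p·s²·(1−hᵢ)²) with
  p = 2 parameters and s² the residual mean square of the full fit.
* p-values below 0.001 are displayed as "<0.001" but stored at full
  precision.  Display rounding for reports: a and b to 2 decimals, PMM to
  1 decimal, peak motorization to 3 decimals; full precision is always
  retained internally.
* Diagnostics on n ≤ 3 points are reported with a warning: the
  leave-one-out variance estimate has no residual degrees of freedom there
  and surfaces as NaN, which never flags.

## Peak-period labelling

"When did the country pass its mortality peak?" is answered by intersecting
the *observed* motorization trajectory with the fitted peak level `1/b`:

* `1/b` below every observed x → `"Before <first observed year>"` (the
  country was already past its peak when the data start);
* above every observed x → `"After <last observed year>"`;
* equal to an observed x within relative tolerance 1e−3 (the 3-decimal
  display precision of peak motorization) → that single year, closest
  match on ties;
* otherwise the pair of observed years bracketing the first crossing,
  labelled `"<year_below>–<year_above>"` — whatever the gap between them,
  so sparse early panels yield decade-wide labels like `"1980–1990"`.

Non-monotone trajectories (possible in real data: vehicle-fleet revisions,
territorial changes) use the first crossing and log a warning.  The label
depends only on the x-trajectory and `1/b`, never on the death counts, so
it is invariant to rescaling deaths.  An alternative definition (year of
maximum observed mortality) was considered and rejected for the default:
it is noise-dominated in exactly the flat-topped region the curve fits
best; the crossing definition reproduces both between-year labels and the
"Before <first year>" labels of countries observed only after their peak.

## Synthetic-data generator

The generator produces country–year panels with precisely the structure
the estimator assumes, so every pipeline stage is testable without any
national dataset:

* motorization follows a monotone trajectory from `x_start` to `x_end` —
  logistic by default (slow–fast–saturating, the shape of real
  motorization curves; steepness 8 on normalized time), exponential as an
  alternative for low-motorization regimes;
* `Y = β₀ + β₁x + ε` with `ε ~ N(0, noise_sd²)` from a seeded generator
  (the seed is a mandatory config field; there is no global RNG);
* deaths, vehicles and population are reconstructed from (x, Y) so that
  the full I/O → transform → fit pipeline recovers the truth exactly when
  `noise_sd = 0`;
* optional point outliers shift single years' Y by a stated multiple of
  `noise_sd`; an emulated 7-day definition divides stored deaths by 1.08
  so the I/O adjustment reconstructs the 30-day values.

Default study conditions: truth (β₀, β₁) = (5.611, −5.742) — i.e.
a = 273.42, b = 5.742, a mid-range national fit, peak at 0.174
vehicles/person; 44 annual observations (1970–2013); motorization 0.01 →
0.35, crossing the peak; `noise_sd = 0.15` (residual spreads are not
published for the national fits, so this is a plausible mid value of the
0.1–0.2 band consistent with the R² range of 0.83–0.98); constant
population 5×10⁷.

What the generator deliberately does **not** emulate: secular
under-reporting trends, mid-series definition changes, autocorrelated
errors, or measurement error in vehicles/population.  Passing tests
therefore demonstrate correctness of the estimator under its own model
assumptions — parameter recovery, coverage, outlier removal — not
robustness of the scientific conclusions to real-world reporting
artefacts.

The fixed per-country coefficient table (15 country/source rows) used by
the reporting and acceptance tests is a worked-example fixture: published
regression coefficients with their derived peak quantities, reproduced by
the package's closed-form functions at display precision.  Because the
printed intercepts carry only 3 decimals, `exp(β₀)` matches the printed
`a` to a relative half-ULP band of 5×10⁻⁴, not to a fixed 2 decimals.

## Simulation experiment designs

Sizes were chosen to give the statistics adequate resolution:

* **Parameter recovery**: 500 seeded replicates at the default conditions;
  mean bias of b̂ bounded by ±0.05 and empirical 95%-interval coverage for
  β₁ required in [0.92, 0.98] (±3 binomial standard errors around 0.95).
* **Outlier pipeline**: 200 replicates with one 10σ-contaminated year.
  Contamination is injected at the final year of an *exponential*
  trajectory — the influential-endpoint design.  The placement matters:
  a contaminated year whose motorization sits near the sample mean has
  essentially no influence on the slope, so removing it cannot
  systematically improve b̂ (the improvement probability degenerates
  towards a coin toss, ≈ Φ(5(x₀−x̄)/√Sxx)).  The endpoint design is the
  regime in which the removal-then-refit procedure is actually expected
  to help, and is also where real reporting artefacts concentrate (the
  most recent year's provisional counts).
* **Flagging sensitivity**: 8σ injections at the default conditions are
  required to be flagged in ≥ 95% of 60 seeded replicates.

## Known limitations

* The curve can only describe series with a rise-then-fall (or monotone)
  shape; multi-peaked mortality histories are outside its family.
* OLS on the log scale weights proportional errors equally across the
  mortality range; countries whose early, low-mortality years are noisy
  in counts will pull the fit there.
* The peak-period label inherits the granularity of the observed panel:
  sparse panels yield wide bracketing labels, and a peak outside the
  observed range can only be bounded ("Before"/"After"), not dated.
* No multiple-testing correction is applied across countries; F tests are
  per-country, matching the single-country inferential use.
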
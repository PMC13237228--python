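# Methods

This note documents the statistical model implemented in `edufert`, the
choices made where the design was genuinely open, what the synthetic
worlds do and do not emulate, and the package's known limitations.

## Estimation pipeline

The goal is a complete lattice of education- and age-specific fertility
rates (EAFR; births per woman per year) over countries, five-year
periods (1970-1975 … 2015-2020 by default), seven reproductive age
groups and four attainment categories, such that the weighted rates are
consistent with an authoritative overall ASFR schedule. Three data
streams inform the fit: survey-derived EAFR observations with birth
counts and person-years exposure, the benchmark ASFR per
country–period–age, and education composition weights summing to one
within each country–period–age cell. A fourth, optional stream —
previously published education-specific TFRs for sub-Saharan African
countries — enters a consistency likelihood.

### Survey cleaning

Three deterministic rules replace the visual screening a human analyst
would apply: (i) rows with education "Higher Education" and a reported
birth count above 30 are dropped (the count is implausible for that
group); (ii) rates above 1.0 births/woman/yr are dropped; (iii) rows
deviating from their country–education–age median by more than 5
normal-consistent MAD units are dropped, iterating rule (iii) to a fixed
point so that cleaning is idempotent. Each removed row is returned with
its reason.

### Step 1: completion GLM

A Poisson GLM with log link on birth counts with a log-exposure offset
(falling back to a Gaussian fit of log rate when counts are absent) uses
the fixed structure

    Education + Region + Age Group + Country + Year
    + Education:Age Group + Year:Age Group
    + Region:Age Group + Region:Year + Region:Country

with every factor categorical (periods included), over the full closed
vocabularies. Because countries nest in regions and some interaction
levels are never observed, the design is rank deficient; a deterministic
sequential column selection on the Gram matrix (main effects scanned
before interactions, relative tolerance 1e-7) keeps a maximal estimable
subset — equivalent to the usual drop-to-estimable convention, but
invariant to row order of the input table. Prediction standard errors on
the rate scale come from the delta method on the linear predictor.
Cells whose combination remains inestimable or numerically unstable
(linear-predictor SD above 5, or a rate outside [1e-7, 5]) receive the
region × education × age marginal mean of the observed rates as center
and the education-median SE, so the Bayesian step always has a finite,
plausible center; these cells are recorded in `aliased_cells_`.

### Prior scale statistics

From the SE lattice the pipeline derives, with sample (ddof=1) moments:
the per-education SD, mean and variance of the SEs; their pooled SD and
variance; the variance of the predicted rates; the per-(age, education)
SD of SEs; the SD of the derived highest-education ETFR; and the
variance-to-mean ratio of the SEs. These parameterize the eight gamma
recipes for the rate precision (`G(shape, rate)` convention):

| name   | shape, rate | grouping |
|--------|-------------|----------|
| final  | 1/σ_e, 2σ_e | education |
| model1 | moment-matched α = mean²/var, β = mean/var of SEs | pooled |
| model2 | 1/μ_e, σ_e² | education |
| model3 | 1/σ_e², σ_e² | education |
| model4 | 1/σ², σ² | pooled |
| model5 | 1/σ_est, σ_est² | pooled (predicted-rate spread) |
| model6 | 1/σ_ae, σ_ae | age × education |
| model7 | 1/σ_e, σ_e | education |

The final recipe's rate is in SD units while the ETFR-precision prior
uses variance units; both are implemented exactly as specified, without
harmonizing the asymmetry. Any statistic that is zero or negative makes
the corresponding recipe raise an error naming the spec and statistic.

### Step 2: hierarchical model

With `N_+(m, τ)` a normal (mean `m`, *precision* `τ`) truncated to the
positive half-line and `N_(0,10)` truncated to (0, 10):

* Level 2: `EAFR_cyae ~ N_+(center_cyae, τ_cyae)`, `τ_cyae ~ G(·,·)` per
  the chosen recipe.
* Level 1: each observed benchmark value
  `ASFR_cya ~ N_+(Σ_e w_cyae·EAFR_cyae, τ^asfr)` with
  `τ^asfr = 1 / Var(benchmark values entering the fit)` held fixed — an
  identity, not a sampled parameter. Cells without a benchmark value
  (the holdout mechanism) contribute no level-1 likelihood.
* Level 3: `ETFR^der_cye = 5·Σ_a EAFR_cyae`;
  `ETFR^est_cye ~ N_(0,10)(ETFR^der, τ^etfr_cye)`; for sub-Saharan
  African countries an observed previous estimate enters the same
  truncated likelihood; `τ^etfr_cye ~ G(1/σ_e4, 2σ_e4²)` built from the
  highest-education ETFR spread and applied to every education level
  (no education-specific alternative is defined).

Derived quantities satisfy their identities exactly per draw:
`ASFR = Σ_e w·EAFR`, `TFR = 5·Σ_a ASFR`, `ETFR^der = 5·Σ_a EAFR`.

### Sampler

Every full conditional is truncated-normal (rates, ETFR estimates) or
gamma (precisions), so posterior sampling is a blocked Gibbs sweep:

* Rates are updated in 7 × 4 (age, education) blocks; cells in a block
  share neither a benchmark row nor an education column and are
  conditionally independent, so each block updates a (country, period)
  array at once via the inverse-CDF truncated-normal draw.
* The ETFR estimate is a leaf node: rate updates marginalize it out and
  it is redrawn from its conditional after each sweep (a partially
  collapsed sweep). Without this, the tight rate–ETFR coupling produced
  a slow random walk; with it, split-R-hat on the default world is
  ≈ 1.01 with bulk ESS in the hundreds from 2 × 1000 draws.
* Precisions use their gamma conditionals. Two deliberate
  approximations: the truncation normalizing constants Φ(m√τ) are
  ignored in the precision updates, and the (0,10) constant is ignored
  when the leaf is marginalized. Both are negligible whenever rates sit
  several posterior SDs above the bounds, which holds by construction
  for fertility scales (rates ~0.005–0.4, totals ≪ 10).

Chains start at the GLM predictions; chain seeds spawn from one root
seed (`numpy.random.SeedSequence`), making runs bit-reproducible.
Diagnostics (split-R-hat, bulk ESS via ArviZ) are computed per cell;
exceeding the 1.05 R-hat threshold attaches a warning, it does not
fail the fit. Default run: 2 chains × (500 warmup + 1000 kept) — about
5 s for the 1,680-cell default world on one CPU.

## Synthetic worlds

The generator emulates the four input streams with a known ground
truth:

* **Truth surfaces**: gamma-density-shaped age schedules over age-group
  midpoints (support above age 10, shape 6), scaled so the no-education
  ETFR in the first period equals a region-specific level (7.0 births
  per woman in sub-Saharan Africa down to 3.0 in Europe), with
  multiplicative education gradients (1.0, 0.92, 0.65, 0.45),
  education-specific peak-age shifts (0, 0.5, 2, 4 years — postponement
  with education) and a log-linear decline of 6% per five-year period.
* **Weights**: education composition interpolating linearly from
  (0.55, 0.30, 0.12, 0.03) to (0.10, 0.22, 0.45, 0.23) across periods
  (education expansion), zero higher-education weight at ages 15-19,
  renormalized to sum to one per cell.
* **Surveys**: each wave observes the periods within its 30-year recall
  window; cell birth counts are Poisson with exposure proportional to
  the education share, `exposure_scale` = 600 person-years per
  country-period base. That figure follows DHS sampling arithmetic: a
  wave interviews roughly 5–10 thousand women, which after splitting
  across 7 age groups, 4 attainment categories and ~6 recall periods
  leaves tens to a few hundred woman-years per cell and rate SEs of
  0.02–0.05 — the noise regime the two-step design is built for. Cells
  below 5 woman-years are unobserved, producing the partial age
  schedules Step 1 must complete.
* **Benchmark**: the weighted truth, optionally perturbed by truncated
  normal noise (default 0: exact consistency). **Previous SSA ETFRs**:
  5 × age sums of the truth plus truncated noise (default SD 0.05).

The default world has 6 countries in 4 regions (2 sub-Saharan), 10
periods, 1,680 cells — sized so the full pipeline, holdout ladder and
sensitivity family run in minutes on one CPU.

Not emulated: survey design effects (clusters, strata, sampling
weights), recall error and age heaping, education-specific reporting
biases, and real revision differences between benchmark vintages.
Passing tests therefore demonstrate internal correctness and
calibration of the machinery, not robustness to those real-data
pathologies. The Poisson-exposure observation model is a stand-in for
the unknown DHS sampling-error law, not a claim about it.

## Validation machinery

* **Holdout plans** delete benchmark cells (a uniform random fraction
  from {5, 10, 15, 20, 30}%, or all cells of named countries), refit,
  and count held-out values inside central equal-tailed 50/80/90%
  intervals of the aggregated-rate posterior (parameter intervals, not
  posterior-predictive draws). Country plans report both pooled and
  omitted-country-only coverage, since either reading is defensible.
* **Generative calibration**: `simulate_from_model` draws a truth from
  the level-2 prior and observations from the likelihoods, keeping the
  observation pattern; fitting those inputs is a well-specified
  inference problem whose 90% intervals should cover ~90% of true
  rates.
* **Alternative benchmark**: the same coverage computation against a
  complete second benchmark (including the 95% level); the acceptance
  script uses a 0.01-SD perturbation of the weighted truth as a
  conventional stand-in for a revision.

On a well-specified synthetic world, holdout coverage is below nominal
and roughly flat in the holdout fraction: a held-out cell's posterior is
the aggregated GLM prior, whose spread understates the GLM's actual
error at that cell. The same sub-nominal pattern appears in the
real-data validation this design mirrors; the package's tests assert
only the two structural properties (monotone in level, non-increasing in
fraction up to binomial error).

## Numerical choices and edge cases

* `G(a, b)` is shape/rate everywhere; `N(m, τ)` is mean/precision.
* Inverse-CDF truncated-normal sampling clips the uniform variate to
  [1e-12, 1 − 1e-12] to avoid infinite quantiles in extreme tails.
* Weight sums are validated to 1e-9 (1e-12 at generation); rates are
  floored at 1e-8 when entering the model as centers.
* The estimates writer enforces the seven-column published schema and
  `Lower_CI ≤ Median ≤ Upper_CI`; readers use round-trip float parsing
  so write→read→write is byte-identical.
* Degenerate statistic groups (a zero SD spread where a prior needs a
  positive scale) raise errors naming the group rather than silently
  producing improper priors.

## Limitations

* The benchmark precision is the reciprocal *cross-cell* variance of
  the benchmark schedule, as the design specifies; it is deliberately
  not a measurement-error estimate, so per-cell benchmark influence is
  modest and holdout coverage under-covers (see above).
* The precision updates' ignored truncation constants would bias
  inference if rates approached zero within a posterior SD; fertility
  lattices do not reach that regime, but the sampler is not suitable for
  near-zero-rate applications as is.
* Model 1 of the sensitivity family often mixes poorly (its
  moment-matched prior is extremely diffuse); it is reported with its
  convergence flag rather than excluded.
* The GLM's Gaussian fallback fits log rates and cannot use exposure
  information; it exists for rate-only inputs and is weaker than the
  Poisson path.
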
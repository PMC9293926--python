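# Methods

## The model

`streamtemp` analyses paired air–water temperature series from a network
of stream monitoring stations nested in catchments.  Water temperature at
site *j*, observation *i*, is modelled as

    Tw_ij = α + (β_air + b1_j)·Ta_ij + Σ_x β_x·x_j + γ_c(j) + b0_j + ε_ij

where `x_j` are site-level environmental covariates (cultivated catchment
area %, Quaternary and pre-Quaternary volcanic geology %, reach elevation,
riparian forest cover %), `γ_c` are fixed catchment contrasts
(treatment-coded against the alphabetically first catchment), and
`(b0_j, b1_j) ~ N(0, D)` is a per-site random intercept and
air-temperature slope with unstructured 2×2 covariance `D`
(τ00² and τ11² on the diagonal).  Catchment is a fixed, not random,
effect: with only four catchments a group-level variance cannot be
estimated meaningfully.

For daily data the residuals within a site follow a continuous-time AR(1)
("CAR(1)") process: `corr(ε_s, ε_t) = φ^|s−t|` with time measured in days.
The continuous form handles irregular spacing and seasonal gaps without
special casing — a gap of Δ days simply contributes correlation φ^Δ.
Monthly series are fitted with independent errors (their residual
autocorrelation is negligible at realistic designs), with time measured in
calendar months; enabling CAR(1) for the monthly model is possible but
warned about.

### Estimation

The marginal likelihood is maximised by REML (default, used for reported
coefficients) or ML (used for model comparison).  Two exact reductions
keep every evaluation O(N):

1. the CAR(1) correlation is removed per site by the gap-aware whitening
   recursion `ε*_k = (ε_k − φ^Δk ε_{k−1}) / √(1 − φ^{2Δk})`;
2. the 2×2 random-effect block is absorbed by the Woodbury identity, so
   only 2×2 factorizations remain.

No N×N matrix is ever formed.  `σ²` and `β` are profiled out in closed
form (GLS); the optimizer works on an unconstrained parameterization —
log-Cholesky factor of `D/σ²` (guarantees positive semi-definiteness),
scaled logit for `φ` (keeps it in [0, 1)).  Optimization runs L-BFGS-B
from three deterministic moment-based starts followed by a Nelder-Mead
polish; multi-start guards against local optima in the variance
components.  The test suite verifies the block likelihood against a dense
stacked multivariate-normal evaluation to 1e-8 and the φ = 0 sub-model
against `statsmodels.MixedLM`.

### Inference

Wald t tests use between-within degrees of freedom: terms constant within
site (catchment contrasts, environmental covariates) are tested against
`n_sites − q_between − 1`; observation-level terms (intercept, air
temperature) against `N − n_sites − q_within`.  The df rule is a
convention, not a derivation from the data; a normal approximation is the
`df → ∞` limit and agrees to 1e-3 in the well-identified regimes the
tests cover.  Nested fixed structures are compared by likelihood-ratio
tests after refitting both models with ML, since REML likelihoods are not
comparable across fixed-effect structures.

The intercept–slope correlation in `D` is estimated, not fixed at zero:
the unstructured 2×2 covariance is the natural reading of a joint random
intercept and slope, even when reports only print the two standard
deviations.

## Variance partitioning

Marginal and conditional R² follow the variance-partitioning convention
for mixed models with random slopes:

    σ²_f = var(Xβ̂)          (fixed effects, estimated coefficients)
    σ²_r = mean_i z_iᵀ D z_i  (random effects, z_i = (1, Ta_i))
    σ²_e = σ̂²

    R²m = σ²_f / (σ²_f + σ²_r + σ²_e)
    R²c = (σ²_f + σ²_r) / (σ²_f + σ²_r + σ²_e)

The adjusted ICC is `σ²_r / (σ²_r + σ²_e)`, identically
`(R²c − R²m)/(1 − R²m)`.  The CAR(1) correlation is ignored in the
partition: it redistributes residual variance over time but leaves the
stationary magnitude σ² unchanged.  Population-level RMSE uses
fixed-effects-only predictions; the conditional RMSE (BLUP random effects
plugged in) is computed for comparison and is never larger when the
random-effect variance is positive.  Variance inflation factors are
computed on the full fitted design with the conventional cut-off of 10;
the multi-column catchment term gets a generalized (determinant-ratio)
VIF.

## Dominance analysis

Relative importance of the five environmental covariates is measured
above a baseline of air temperature + catchment with the random and
correlation structure held fixed; every subset model re-estimates its own
variance components (freezing them at full-model values is available as
an option through the engine abstraction).  The fit statistic is marginal
R², each subset model using its own denominator, the convention of the
all-subsets relative-importance literature; a shared-denominator variant
would change the numbers slightly but not the machinery.  Additional
contributions may be negative under refitting and are retained as-is.

Pairwise dominance is classified at three hierarchical levels — complete
(greater contribution in every subset excluding both predictors),
conditional (greater size-k mean for every k), general (greater overall
average) — with strict inequality required at every level; exact ties
yield "none".  The general-dominance weights are the Shapley values of
the R² game (verified against direct permutation enumeration to 1e-10)
and sum exactly to the baseline-to-full R² increment; relative importance
expresses them as percentages of that increment.

## The synthetic generator

The generator emulates a 130-station, four-catchment summer monitoring
network: hourly air temperature as a site mean (with a weak elevational
lapse) plus annual and diel sinusoids plus AR(1) noise; water generated
from the mixed model above with CAR(1) residuals built by the exact
gap-aware recursion (stationary variance σ² under any gap pattern);
missingness injected in geometric bursts (mean 12 h, emulating logger
failures) at an expected 1.8% rate per channel.  Covariate distributions
are bounded — scaled Betas for percentages, truncated log-normal for
elevation — and configurable; nothing constrains cultivated and forest
fractions to sum to 100 because they describe different spatial supports.
Default truth parameters (α, β_air, covariate coefficients, catchment
offsets, τ00, τ11, σ, φ = 0.962 daily) are fixed per timescale at the
values of the regime the package targets; the intercept–slope correlation
defaults to 0.  Seeding is hierarchical: a master seed spawns one
independent stream per site, so the series of existing sites are
untouched when the site count changes.

In the end-to-end pipeline, water responds to a low-pass-filtered
(exponential moving average) version of hourly air with a 6 h time
constant, emulating the thermal inertia of small streams.  This is what
makes the fitted air slope scale-dependent: the daily CAR-GLS estimator
keys on high-frequency air variation, which the filter attenuates, while
monthly means align with the smoothed driver.  At the default the
daily/monthly slope ratio is ≈0.65.  A longer time constant (36 h)
collapses the daily slope by an order of magnitude — a useful reminder
that the printed slope at a given timescale is a property of the
estimator's frequency window as much as of the stream.

### What the generator does not emulate

* Covariates are drawn independently of each other and of catchment.
  Real monitoring networks have strong covariate correlation structure
  (elevation with geology, riparian cover, and catchment), which shrinks
  each covariate's unique contribution.  With independent covariates at
  the default coefficients, reach elevation carries by far the largest
  dominance share, because its between-site effect variance
  (≈0.044 °C/m × tens of metres) dwarfs the geology and riparian terms.
  Passing tests therefore demonstrate the correctness of the machinery,
  not that any particular field share ordering is recoverable.
* No spatial correlation between sites along the river network, no
  hydrology beyond the statistical structure above, and no genuine
  air-exposure events (the screening heuristic is exercised on
  constructed fixtures).

## Validation studies and the problem sizes used

`streamtemp.studies` packages the Monte-Carlo checks; the acceptance
script reruns them from scratch:

* **Monthly slope recovery** — 50 replicates of 130 sites × 10 monthly
  observations; mean relative bias of β̂_air and 95% Wald coverage.
* **CAR φ recovery** — 20 replicates of 50 sites × 120 daily
  observations at φ = 0.8; also the identity that the CAR likelihood at
  φ → 0 equals the independent-error likelihood.
* **Type-I calibration** — 500 replicates of 40 sites × 6 observations
  with a null site-level covariate; rejection rate of the between-within
  t test at p < 0.05.
* **Timescale dominance contrast** — 20 replicates of a compact
  two-covariate design (60 sites; 90 daily vs 10 monthly observations)
  in which the riparian effect lives entirely at the daily scale (its
  coefficient plus a riparian-proportional zero-mean day-to-day variance
  channel) while the geology shift is persistent; the share of geology
  should be higher in the monthly analysis in at least 80% of
  replicates.  Because a purely high-frequency effect leaves no
  persistent monthly signal, the monthly truth sets the riparian
  coefficient to zero; between-site variance components are scaled down
  (τ00 = 0.4) and the daily memory shortened (φ = 0.8) so the share
  estimates are stable at this design size.

These sizes keep a full validation pass in the ten-minute range on one
core while staying at, or close to, the design scale of the target
network.

## Numerical conventions and degenerate inputs

* The aggregation threshold comparison is inclusive (≥ 0.75); expected
  hours are full calendar hours (24/day, leap-aware per month) even for
  partially covered units; monthly means are computed from hourly data,
  never as means of daily means; pairing drops half-missing periods.
* Duplicate time points within a site are a data error under CAR(1), not
  silently averaged; duplicate (site, period) records are always errors.
* A catchment factor constant after subsetting is dropped with a
  warning; a singular fixed design raises with the collinear columns
  named.
* Perfectly collinear VIF terms are reported as infinite and flagged.
* R²/ICC with zero total variance raise rather than return NaN.
* A dominance run whose baseline-to-full increment is not positive
  reports weights but no percentage shares (with a warning).

## Known limitations

* Degrees of freedom are the between-within convention, not
  Satterthwaite/Kenward-Roger; for heavily unbalanced designs the t
  tests will be approximate.
* The Wald covariance of β̂ conditions on the estimated variance
  components; no finite-sample correction is applied.
* Air-exposure screening is a heuristic (diel-range inflation plus
  air-tracking) and off by default; it replaces a visual-inspection
  step and has no claim to sensitivity beyond its constructed fixtures.
* Dominance requires every subset model to converge; a failed subset
  aborts the analysis by design rather than imputing its R².
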
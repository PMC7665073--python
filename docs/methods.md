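# Methods

## Growth-trial statistics

The tank is the replicate unit.  Every metric — absolute and percent
weight gain, FCR, SGR, PER, survival — is computed per tank and then
averaged within a diet; the reported SE is sd/√n over tank-level values.
The ratio-of-means alternative (computing, say, SGR from the diet-mean
initial and final weights) is deliberately not used: it answers a
different question and is not the estimator that matches "mean ± SE of
n = 3 replicate groups" reporting.  The two conventions disagree
noticeably for convex metrics (WG%, SGR), which is why group-mean tables
generally cannot be inverted exactly back to the per-tank statistics.

Trial duration is a required explicit field on every tank record
(the simulator defaults to 184 days).  Feed intake and protein fed are
stored per fish; when converting a tank-total feed mass, divide by the
mean fish count (n_initial + n_final)/2 — a documented convention, since
mortality makes "per fish" ambiguous.

FCR is undefined for non-positive gain and raises a dedicated error
rather than dropping the tank: a shrinking tank is a finding, not a
missing value.

## ANOVA and compact letter display

`anova_oneway` is the classical pooled-variance fixed-effects one-way
ANOVA; no Welch correction (group variances are assumed homogeneous, the
standard assumption for small balanced tank designs).  Tukey HSD pairwise
p-values come from the studentized range distribution with the
Tukey–Kramer standard error, cross-checked in the test suite against
statsmodels' `pairwise_tukeyhsd`.

`anova_from_summaries` reconstructs the same analysis from published
(mean, SE, n) rows using sd² = n·SE², pooling within-group variance with
df weights.  For balanced raw data the two routes agree to numerical
precision, so printed summary tables can be re-analysed directly.
Reconstruction from *rounded* printed summaries carries the rounding into
F (e.g. a printed F of 4.7 reconstructs as 4.76 from one-decimal means
and SEs); exact agreement would require the unrounded per-tank data.

Letters are assigned by the insert-and-absorb construction: start with
one column holding all groups, split every column containing a
significantly different pair, drop absorbed (subset) columns, then letter
columns in order of descending maximum group mean.  This guarantees the
display property tested in the suite: significant pairs share no letter,
non-significant pairs share at least one.  α defaults to 0.05 and is
configurable.

Degenerate inputs: identical group means give F = 0, p = 1; zero
within-group variance with distinct means reports F = ∞, p = 0 with a
warning rather than an exception.

## pH-stat digestibility

Stomach phase (pH 2.0, 25 °C): DH% = (V·N/E)·(1/P)·F_pH·100 with
P = 8.0 mol peptide bonds/g protein when the amino-acid composition is
unknown and F_pH = 1.08.  Intestinal phase (pH 8.0, 25 °C):
DH% = B·N_b·(1/a)·(1/MP)·(1/H_tot)·100 with 1/a = 1.50 and H_tot in
[7.6, 9.2] meqv/g protein depending on the substrate; the default is the
midpoint 8.0, and values outside the range are rejected unless explicitly
overridden.  Titrant volumes may be supplied as a total or as an
auto-titrator dosing log, which is summed.

Predicted digestibility is the linear calibration IPD = 3.5093·DH +
70.248.  Which phase's DH feeds the prediction is configurable
(`intestine` default, `stomach`, or `sum`); the calibration the equation
derives from is built on intestinal-phase hydrolysis.  Both DH forms are
linear in titrant volume and inversely proportional to substrate protein
mass, properties the suite tests directly.

## Hedonic pricing

Meal model (price in USD/tonne, composition standardized):

    y = β0 + β1·CP² + β2·Met² + β3·Lys² + β4·EE
        + u0(yr) + u1(yr)·CP + u2(yr)·EE + ε

Oil model: fixed effects {EPA², 14:0², 16:1n-7², 14:0, 16:0} with
year-level intercept and slopes on 14:0 and 16:0.  Estimation is maximum
likelihood via statsmodels MixedLM (REML behind a flag).  The notation
sometimes used for such models — two separate covariate-labelled random
*intercepts* per year — is not identifiable with a single year grouping
(only their sum enters the likelihood), so the implementation carries one
year-level random intercept plus the two random slopes.  The default
random-effects covariance is diagonal (independent variance components):
with only ~10 grouping levels a free 3×3 covariance is weakly identified;
a `cov_structure="free"` option exists and falls back to diagonal with a
warning if the free fit is singular.

Numerical choices: MixedLM convergence is optimizer-sensitive here, so
fitting walks lbfgs → bfgs → powell → cg and errors only if none
converges.  Panels with a single year, or with numerically zero residual
variance (noise-free simulations), drop to an OLS fixed-effects fit with
a warning — in that limit the GLS fixed-effect solution coincides with
OLS, so recovery identities are preserved.

Composition variables are standardized (x − center)/scale.  Defaults are
the panel mean and *population* SD (invariant to repeating each
commodity's constant composition across years); external scaling
parameters can be injected and travel with the fit.  Predictions evaluate
the fitted polynomial at the scaled target; `marginal` zeroes the random
effects, a specific year adds that year's realized coefficients, and
`predict_per_year` gives the across-year price distribution.  Pricing a
novel ingredient is usually extrapolation in at least one attribute; this
is permitted but logged whenever a scaled variable leaves the observed
panel range by more than 25% of its span.

Freight: landed price = source price + Σ_mode share·rate·distance over
domestic modes + ocean rate·distance.  Whole-cell conversion multiplies
an oil price by the organism's lipid mass fraction (0.54 for
*Schizochytrium* sp.): the oil embodied in the biomass is the value
carrier.

## Feed cost, ECR and the bootstrap

Feed cost is Σ (inclusion g/100 g)·(price USD/kg); inclusions must sum to
100 ± 1 g and every included ingredient must be priced (errors name the
offender).  ECR = FCR × feed price.

Uncertainty: ingredient prices supplied as samples of (annual)
observations are bootstrapped nonparametrically — each replicate
resamples every ingredient's observations, takes its median, and
recomputes the feed cost; the ECR replicate multiplies that cost by a
resampled tank FCR, propagating price and between-tank variation jointly.
Reported intervals on scalar medians use the BCa ("adjusted percentile")
method with 10,000 replicates by default (scipy's implementation),
deterministic under a given seed.  Constant samples collapse the CI to
the point; near-degenerate samples (≤ 2 distinct values) warn that the
jackknife acceleration is unstable; if BCa itself degenerates (all
resampled medians tie), the interval falls back to plain percentiles with
a warning.

The cross-diet ECR ANOVA uses the tank as replicate: per-tank
ECR = tank FCR × the diet's median feed cost.  The per-ingredient
disaggregation is built from median ingredient prices and the diet-mean
FCR, so contributions sum *exactly* to the point ECR (an invariant the
suite asserts at 1e−9) — the bootstrap median of a sum is not the sum of
medians, so the decomposition is defined on the point scale.

## Synthetic data

Each generator inverts its analysis stage, so zero-noise simulation
followed by analysis is the identity on the configured truths, and all
generators are bit-reproducible under a seed.

- **Trial**: per-tank initial weight ~ N(34.5, 2.06²) g; final weight
  from the diet's true SGR via W_f = W_0·exp(SGR·t/100) with lognormal
  tank noise (sd 0.08 on the growth factor — chosen so simulated SE/mean
  of weight gain lands in the ~5–13% range typical of triplicate tank
  trials); feed from true FCR × gain with lognormal sd 0.05; survivors by
  binomial thinning (default mortality 0.06 per trial).  Default truths
  are the four observed diet outcomes (SGR 0.62/0.81/0.74/0.87 %/day,
  FCR 1.61/1.57/1.60/1.40); 4 diets × 3 tanks × 40 fish, 184 days.
- **Panel**: compositions uniform within per-variable ranges wide enough
  that the novel microalgal ingredients are interior points (so pricing
  them in tests is interpolation, and extrapolation only when
  configured); year effects from centered normals (SDs 30/15/15
  USD/tonne); residual ε ~ N(0, σ) with σ defaulting to 5% of the mean
  model price.  Prices are floored at 10 USD/tonne with a warning.  The
  generating coefficients are returned alongside the panel for recovery
  testing.
- **Titration**: the titrant volume implying the configured true DH is
  computed exactly per phase, then Gaussian dosing noise (default
  0.02 mL) is added; triplicate by default.

What the simulations do not emulate: individual-fish growth dynamics and
size hierarchies, water-quality covariates, serial correlation in
commodity prices (year effects are exchangeable, not a random walk), and
composition measurement error.  Passing recovery tests therefore
demonstrates the estimators are correct for the assumed data-generating
structure, not that the structure captures every feature of real markets
or husbandry.

## Problem sizes

The recovery simulation fits 200 panels of 12 commodities × 10 years;
bootstrap coverage uses 100 runs of 10,000 replicates on n = 200 samples.
The full default test suite runs in well under a minute on one CPU.

## Known limitations

- Reconstructed ANOVAs inherit the rounding of published summaries.
- BCa intervals for medians of small samples (n ≲ 10) are unstable;
  warnings flag the degenerate cases but wider intervals should be
  expected there.
- The hedonic CI coverage relies on asymptotic normal standard errors of
  the fixed effects; with 10 year levels, coverage is slightly below
  nominal (≈ 91–94% observed at 95% nominal in the suite's simulation).
- Combining tank-FCR and price uncertainty into one ECR interval is a
  modelling choice (independent resampling); correlated feed-price and
  performance shocks are out of scope.
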
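# Methods

This note records the models, the synthetic ground truth, the numerical
choices, and the places where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The exposure model

The pollution exposure index (PEI) of chemical *k* at location *i* is a sum
over the *n* emission sources of a learned per-source contribution
*g*(T, H, EM, D, ED, W). The six inputs are:

| symbol | meaning | units | transform for the network |
|---|---|---|---|
| T | temperature at the receptor | °C | identity |
| H | relative humidity at the receptor | fraction 0–1 | identity |
| EM | fugitive + stack emission of *k* from source *j* | kg/yr | log1p |
| D | receptor–source planar distance | km | log1p |
| ED | source elevation − receptor elevation | m | identity |
| W | wind index (below) | dimensionless 0–1 | identity |

All transformed inputs are z-standardized; the scaler fitted on the training
rows is stored with the model so prediction-time features are scaled
identically. EM and D get log1p transforms because both are heavy
right-tailed; raw values are kept in the feature tables for reporting.
Zero-emission (source, chemical, year) pairs are dropped from the sum: no
emission, no contribution, and the training targets stay clean. Slope and
aspect can be derived from the terrain model but are not network inputs by
default — the contribution function is defined on exactly six variables.

**Wind index.** No standard closed form exists for "how often the wind
carries material from *j* to *i*", so the package defines
`W = Σ_s f_s · max(0, cos(θ_s − θ_{j→i}))^p` over the 16 compass sectors of
the wind-direction histogram at the *source*, where `f_s` are sector
frequencies and `θ_{j→i}` is the source-to-receptor bearing; the exponent
*p* defaults to 1. W is 1 when the wind always blows along the bearing, 0
when it never has a component toward the receptor, ≈1/π for a uniform rose,
and is equivariant under joint rotation of histogram and bearing.
Coincident points get W = 1 by convention. The choice is monotone in the
quantity it is meant to capture; any alternative with the same monotonicity
would serve.

**Network and training.** g is a multilayer perceptron with hidden layers
(16, 8), tanh activations, and a softplus output, so every contribution is
non-negative and PEI is non-negative and *exactly* additive over source
subsets (a structural property, independent of the weights). The loss is
mean squared error between the *summed* contributions at a monitor site and
the measured value — the sum sits inside the loss, and gradients flow
through the shared network applied to every source row of the site. By
default the loss is computed on the log1p scale of both prediction and
target: monitor values inherit the log-normal emission tail, and a raw-scale
MSE lets a handful of high-concentration sites dominate the fit (the raw
scale remains available via `TrainConfig.log_target=False`).

Optimization is full-batch Adam (base learning rate 0.03, up to 400 epochs)
with two guards: an uphill step is reverted and retried at half the learning
rate (the rate recovers by 5%/accepted step up to its base), which makes the
recorded loss trajectory non-increasing by construction; and early stopping
(patience 50 epochs, checked every 5) on a validation split of 10% of
*sites*, not records. The output bias is initialized so that the summed
initial contributions match the mean target — with hundreds of source rows
per site, a default softplus output (~0.69 per row) would otherwise start
orders of magnitude above the data. All randomness (initialization, splits)
derives from one integer seed; training is bit-reproducible.

**Calibration.** After training, predictions are rescaled onto monitor units
by least squares through the origin. The scale is folded into g itself, so
`PEI = Σ g` stays exact and additivity is preserved; an affine calibration
(with intercept) would break both, which is why the rescale is
multiplicative only. Pearson/Spearman cross-validation statistics are
invariant to it.

**Pruning.** "Pruned" is implemented as iterative global magnitude pruning:
at each step of the schedule (cumulative fractions, default 0.3 then 0.5)
the smallest-magnitude surviving weights across all layers are masked to
exactly zero, the survivors are retrained, and the step is kept only while
the site-split validation loss stays within (1 + tolerance) of the
pre-pruning loss (tolerance 0.10). Masked weights stay zero through any
retraining. Biases are never pruned.

**Cross-validation.** k-fold (default 10) over *sites*: every record of a
monitoring site shares a fold, so a site never appears in both train and
test — spatial leakage through site identity is excluded. Each fold trains
a fresh model with its own scaler on the remaining sites. The report gives
per-fold Pearson and Spearman correlations between predicted PEI and
held-out measurements.

## Grid prediction and aggregation

PEI is evaluated at the centroids of a 4050 m grid covering the study
rectangle (rows/cols = ⌈extent/cell⌉, so a boundary ring may overhang).
Per-area exposure is the unweighted mean of the cells whose centroids fall
inside the area — the population is assumed evenly distributed within each
small area, matching the outcome data's resolution. Centroids on a shared
boundary belong to the area with the lexicographically smallest id, a
deterministic half-open rule. An area too small to contain a centroid falls
back, with a warning, to an area-weighted mean over the cells it intersects;
an area with no grid coverage at all is an error naming the area. Annual
area values are averaged over years with equal weights.

## Covariates

Tract-level *counts* (population; female; less-than-high-school; unmarried;
four race/ethnicity categories) are reaggregated to small areas by simple
area weighting of polygon intersections, then converted to percentages of
the interpolated population. Counts, never rates, are interpolated, which
makes every column mass-conserving (the pycnophylactic property) — total
population is preserved to floating-point accuracy. No dasymetric
refinement is attempted. Regressions consume K−1 race shares (reference:
white) to avoid exact collinearity with the intercept.

## Association models

For each chemical: OLS of the small-area LBW rate (% of births) on
exposure/IQR plus the covariate block. The IQR is Q3 − Q1 with
linear-interpolation ("type 7") quantiles — recorded so exposures can be
re-scored identically elsewhere. The reported effect is the coefficient on
the IQR-scaled exposure: percentage-point LBW-rate change per IQR increase.
Intervals are symmetric Wald intervals from the t distribution on residual
degrees of freedom, so the effect is always the interval midpoint. The
headline model is covariate-adjusted; the univariable fit is available by
passing no covariates. Regression is unweighted across areas; weighting by
births is a deliberate non-default (areas are built to similar populations,
and the generating model is homoskedastic on the rate scale).

**Multiple comparisons.** `bh_adjust` implements the Benjamini–Hochberg
step-up rule: find the largest rank *r* with p₍ᵣ₎ ≤ r/m·FDR; all tests
ranked ≤ r are significant. It returns, separately labelled, the per-rank
critical thresholds r/m·FDR *and* the monotone adjusted p-values
min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j — two different objects that published tables sometimes
conflate. A variant (`step_up=False, strict=True`) compares each ordered
p-value only to its own rank threshold with strict inequality and no
propagation; some published small-area analyses use this rule, and on the
worked-example table the two rules genuinely disagree: the fifth-smallest
p-value (0.025) exactly equals its rank-5 threshold, so the step-up rule
flags five chemicals where the per-rank rule flags two (mercury, chromium —
the calls the table itself marks). The package computes both and never
substitutes one for the other silently.

**Two-pollutant models.** For a primary chemical, the design adds a second
IQR-scaled exposure plus the covariates; the primary coefficient is
reported. Pairs are screened by |Pearson r| < 0.5 on the multi-year mean
exposures — absolute value, because a strong negative correlation confounds
the fit as much as a strong positive one.

## The synthetic ground truth

The plume surrogate is

`C(i) = s · Σ_j EM_j · exp(−D_ij/λ) · (1 + a·W_ij) · u(ED_ij) · m(T_i, H_i)`

with decay length λ = 15 km, downwind gain a = 1, modifiers
`u(ED) = 1 + 0.25·tanh(ED/400 m)` and
`m(T,H) = 1 + 0.25·tanh((T−13 °C)/10) − 0.25·tanh((H−0.5)/0.3)` (both within
[0.5, 1.5]), and an arbitrary output scale s = 10⁻³ defining the
concentration-index unit — the measurement units of the training data are
deliberately left abstract. At D = 0 the alignment factor is defined as 1,
which leaves a removable discontinuity at the source itself; monotone
distance decay holds for all positive distances. The surrogate is *not* an
atmospheric model: no chemistry, deposition, plume rise, or hourly
meteorology. It is smooth, cheap, exactly additive over sources, and has the
qualitative structure (distance decay, downwind enhancement, terrain/climate
modulation) the network must learn — which is precisely what makes recovery
a meaningful test.

Study-condition defaults mirror the target analysis: 5 years, 108 small
areas on a 400×400 km extent, 369 facilities, 63 monitoring sites, ten
metals. Small areas are Voronoi cells of points rejection-sampled from an
urban Gaussian-mixture population density (areas built on population, not
land); tracts are an independent, finer partition of the same density.
Monitor sites and most facilities are drawn from the same density, so
monitors cluster in "urban" places — and, as in real networks, remote areas
are less constrained by training data. A (facility, chemical) pair is a
structural zero with probability 0.7 (facilities release only a few of the
ten metals); reported masses are log-normal (log-mean 5, log-sd 1.5, mild
year jitter), split into fugitive and stack shares. Monitor noise is
multiplicative log-normal with unit mean and coefficient of variation 0.15
by default; `noise_cv=0` reproduces the oracle exactly.

Outcomes invert the regression: `rate = β₀ + Σ_k β_k·X̄_k/IQR_k +
γ·(C − C̄) + ε` with baseline 9% (reduced by centred covariate terms to land
in the observed 6–13% band), injected effect β_mercury = 0.43 %/IQR by
default (examples also inject chromium 0.63), Gaussian noise with SD 0.6
percentage points on the rate scale (the fitted model's own assumption), and
rates clipped to [0, 100] (never binding at the defaults). The covariates
entering the generator are the *same* areally interpolated values the
association stage later adjusts for, so the noiseless round trip recovers
every injected β to machine precision — the key identifiability check. The
`TruthBundle` stores the per-area oracle exposures (averaged on the same
grid/rule as the pipeline), the injected effects, and the IQRs; pipeline
stages never read it.

What passing these tests does *not* show: performance under real atmospheric
transport, reporting errors in emission inventories, spatially correlated
outcome noise, or confounding structures absent from the generator (the
synthetic covariates are independent of exposure by construction, so
adjustment is exercised for correctness, not for confounding control).

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation throughout (IQR, generator calibration).
- A zero IQR (constant exposure) is an error wherever a per-IQR effect is
  requested; rank-deficient designs raise with the collinear columns named.
- Voronoi cells are bounded by mirroring seeds across the rectangle edges;
  the cells tile the extent to float accuracy. One area degenerates to the
  extent rectangle.
- ESRI ASCII grids are written with `repr` floats (lossless round trip);
  CSV reads use round-trip float parsing.
- Additivity assertions allow 1-ulp float re-association; the structure
  itself is exact.
- Training raises on non-finite loss rather than continuing silently.
- Stochastic test thresholds are set at ≥3 binomial/Monte-Carlo standard
  deviations from nominal so a correct implementation fails with
  probability ~10⁻³.

## Problem sizes used by tests and the acceptance script

Unit tests run on compact worlds (12–30 areas, 40–120 facilities, 15–25
sites) chosen so the whole non-acceptance suite finishes in seconds while
still exercising every code path. The acceptance checks run the exposure
model at the full default conditions (63 sites × 10 chemicals × 5 years,
369 facilities): 10-fold site-level cross-validation there trains 100
networks and dominates the runtime of both the test suite and
`scripts/acceptance.py` (minutes). Confidence-interval coverage uses 200
outcome replicates on the default 108-area region with exposures computed
once from the oracle on the 4050 m grid.

## Known limitations

- The plume surrogate's simplicity means the network's task is easier than
  real exposure assessment; cross-validation numbers on synthetic data
  bound the method's plumbing, not its field accuracy.
- One network per chemical is the default; a shared network with chemical
  encoding is plausible but untested here.
- Emission "time" is the annual label only; no sub-annual structure.
- Mobile, areal and line sources, and sources outside the inventory, are
  out of scope; so are spatial autocorrelation models (CAR/SAR) and
  individual-level outcome models.
- Real-data adapters must supply an equal-area projection; all internal
  geometry is planar meters.
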
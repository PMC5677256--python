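# Methods

## Yield models

The core response model is a second-order polynomial in the two stressors
(boron and salinity) with linear leaching-fraction and water-content terms:

    Y = β₀ + β₁B + β₂B² + β₃EC_e + β₄EC_e² + β₅LF + β₆θ_g + ε

with Y the oilseed yield (kg/ha), B the root-zone (0–1.2 m composite)
saturation-extract boron (mg/L), EC_e the saturation-extract electrical
conductivity (dS/m), LF the leaching fraction (dimensionless) and θ_g the
gravimetric water content (kg/kg).  The concavity in B and EC_e encodes the
agronomic observation that moderate osmotic stress pushes the plant toward
reproductive (seed) rather than vegetative growth, so oilseed yield peaks
at interior stressor values (B = 4.0 mg/L, EC_e = 6.8 dS/m under the
default coefficients) and declines on both sides.  Polynomial predictions
are truncated below at zero: negative yields are unphysical and would leak
into regional production totals.

The default coefficients (30.1, 146.4, −18.3, 83.0, −6.1, 1301.0, 319.8)
are the published spatially-adjusted fit; their applicability ranges are the
min/max of the 34 positive-yield trial sites (EC_e 1.84–29.97 dS/m,
B 2.14–24.24 mg/L, LF 0.08–0.61, θ_g 0.12–0.25), checked inclusively.

Where the full model cannot be applied, the tolerance curves take over:

* **Two-piece linear salt tolerance** (threshold-slope): relative yield is
  100% up to the threshold a = 8.3 dS/m, then declines b = 17% per dS/m,
  floored at 0.  Under these defaults the computed zero-yield salinity is
  a + 100/b = 14.18 dS/m (the one-decimal rounded figure in circulation,
  14.3, is not forced: the package computes).
* **Three-piece linear boron tolerance**: optimum plateau 4.2–8 mg/L,
  toxicity decline 28% per mg/L (zero yield at 8 + 100/28 ≈ 11.6 mg/L).
  The deficiency-side slope is not published; the default (100/4.2 ≈
  23.8 %/mg/L) is the slope implied by zero yield at B = 0 rising to the
  plateau at 4.2 mg/L, and is configurable.
* **Quadratic tolerance curves** for both stressors
  (Y = 74.0 + 254.6·EC_e − 18.8·EC_e², Y = 555.2·B − 42.4·B² − 418.0), an
  alternative curve family selectable throughout the simulation.

### Model selection

Per location, availability and range of the inputs select the model: the
full regression when all four regressors are present, in range, and the
texture is fine (the regression was developed on a fine-textured field);
the tolerance curves otherwise, taking the *minimum* of the salt and boron
relative yields ("most limiting") when both stressors are known; the salt
curve alone when only salinity is known; and an optimal (plateau) yield
when neither stressor is known.  A location with boron data but no salinity
is routed to the tolerance path with the absent stressor treated as
non-limiting — the same convention as "boron assumed optimal when absent",
applied symmetrically — which keeps the selection function total.

Tolerance-curve relative yields are converted to absolute yields by a
plateau yield `y_max`, default 936 kg/ha: the vertex value of the quadratic
salt-tolerance curve.  The plateau yield actually used in the original
analysis is not recorded, so this is an explicit, configurable convention.

## Fitting

`FullYieldRegression` fits the polynomial by OLS (statsmodels).  Backward
t-screening drops, one at a time, the predictor with the smallest absolute
t-score while that score is below 1.8, refitting after each drop;
ties break by the fixed candidate ordering, and an empty surviving set
returns an intercept-only fit with a warning.  An optional generalized
least squares refit with an exponential distance-decay error correlation
exp(−d/range) stands in for a spatially-adjusted likelihood fit; the exact
spatial covariance of the original analysis is not recoverable, so the GLS
option is documented as an assumption and nothing downstream depends on it.

Piecewise tolerance curves are fitted by deterministic grid search over
breakpoints (default step 0.05 in stressor units) with the plateau fixed at
100%: for each candidate threshold the declining slope has a closed-form
least-squares solution, so the search is exact over the grid.  For the
three-piece boron curve the total squared error separates into a
deficiency-side term (lower threshold only), a toxicity-side term (upper
threshold only) and a plateau constant, so the two thresholds are searched
independently, with a constrained joint search as fallback if the
independent minimisers cross.  Candidates need at least two points and a
positive fitted slope on the declining side; otherwise the fit reports
no-decline or segment-underdetermined errors rather than extrapolating.

## Input uncertainty

Regional salinity predictions carry category-dependent error.  The residual
table stores, per 1 dS/m bin of predicted EC_e (half-open bins [k, k+1),
open above 16), the mean and SD of prediction residuals, plus a pooled
whole-dataset row (mean 0.14, SD 3.11 dS/m, n = 4311).  Residuals are
*predicted − observed* — the sign convention under which the strongly
positive high-category means correct the known over-prediction of high
salinity — so a sampled salinity is the prediction minus a normal residual
draw, truncated at zero.  The pooled row is the default sampling mode
(category-wise sampling gives materially similar regional results and is
available as `residual_mode="category"`).

B, LF and θ_g are sampled from lognormal PDFs parameterised by natural-scale
mean and SD via moment matching (σ² = ln(1 + (sd/mean)²),
μ = ln(mean) − σ²/2).  Defaults are the trial marginals (B 10.03/6.06 mg/L,
LF 0.27/0.15, θ_g 0.19/0.05), explicit stand-ins for the unpublished
long-term regional dataset behind the original PDFs.  Survey-database
(SSURGO-style) bounds attached to a field truncate the draws by rejection
resampling (clipping would pile mass on the bounds); LF and θ_g are
additionally capped at 1.  A field "has" a variable when per-field PDF
parameters or bounds are attached to its record; absent variables are
treated as non-limiting in the tolerance path.

Leaching-fraction estimation helpers implement the two field methods — the
horizontal/vertical electromagnetic-induction reading ratio and the
irrigation-to-deep-percolate chloride ratio, both clipped to [0, 1] — and a
reconciliation rule that accepts the mean of the two estimates only when
they agree within 5%.  Agreement is interpreted as *relative* difference
(the alternative, absolute difference, is not distinguishable from the
available description; relative is the stricter reading at small LF).

## Monte Carlo simulation

The simulation unit is the field (area-weighted), not the 30 m raster
pixel: under the stated PDFs a field is statistically exchangeable with its
pixels, and field-level records keep a full 10,000-iteration run on a
single CPU in seconds.  Fields are first filtered to salt-affected cropland
(predicted EC_e ≥ 4 dS/m inclusive; orchards and vineyards excluded because
the regional salinity model over-predicts there).  Each iteration draws
salinity and available inputs per field, applies the model-selection
hierarchy vectorised over iterations, converts oilseed yield to biofuel
volume (26% oil content × 64% extraction efficiency; the volumetric factor
is stored as the printed 175.3/166.4 L/kg ratio rather than an assumed fuel
density), and aggregates Q = Σ areaᵢ·volumeᵢ/10⁶ ML/yr.

Random streams are derived per field and per variable from the master seed
(spawn keys from a CRC-32 of the field id), so adding or removing fields
never perturbs other fields' draws; this enables common-random-number
comparisons (e.g. raising one field's predicted salinity, everything else
fixed).  Identical seed and configuration give bitwise-identical totals.

Summary statistics report skewness and kurtosis as standardized third and
fourth central moments, kurtosis on the *non-excess* scale (normal = 3).
An intercropping scenario (oilseed planted between orchard rows, an
estimated 15–30% regional uplift) is a linear scaling of every total.

## Feasibility statistics

Simulated production is summarised by a shifted gamma
Q = shift + Gamma(shape, scale), with analytic moments
mean = shift + shape·scale, sd = √shape·scale, skewness = 2/√shape,
kurtosis = 3 + 6/shape.  The default fit method is method of moments
(deterministic; matches sample mean and SD by construction and requires
positive sample skewness); a profiled-shift maximum-likelihood method is
available, maximising the gamma likelihood over a shift grid below the
sample minimum.  The exceedance probability P(Q ≥ target) is the
regularised upper incomplete gamma function at (target − shift)/scale, and
is also reported empirically as the sample fraction at or above the target.

The package ships the published full-region production law
Q = 68.986 + Gamma(6.134, 5.285), whose analytic mean is 101.40 ML/yr and
whose exceedance probability at 115 ML/yr evaluates to 0.146.  Its analytic
SD/skewness/kurtosis (13.09 / 0.81 / 3.98) differ somewhat from the
summary values reported alongside it in the original study (14.1 / 0.87 /
4.14); that discrepancy is unresolved at the source, so only the mean is
treated as a hard reference.

## Synthetic data

The generators define the study conditions for every test:

* **Trial generator** — 40 sites (6 forced to zero yield) on a jittered
  grid; edaphic marginals lognormal with the trial means/SDs (optionally
  spatially correlated through an exponential-covariance Gaussian copula);
  yields are the polynomial plus Gaussian noise (default SD 100 kg/ha,
  ~10% of the baseline yield), truncated at zero; the forced zero-yield
  sites are placed at the highest generated salinities, where the real
  zero-yield sites sat.  Under independent marginals part of the generated
  design space produces zero yields that the fitting step excludes, so
  noisy parameter-recovery checks are ensemble statements over seeds rather
  than single-draw 3-SE assertions.
* **Region generator** — default 1000 fields totalling 9.7×10⁴ ha (a tenth
  of the real region's salt-affected area, a desk-scale choice); predicted
  salinities drawn uniformly within residual-table categories with mixture
  weights proportional to the category data counts; lognormal areas
  rescaled to the exact total; 15% coarse texture, 5% orchards/vineyards,
  80% availability for each of B, LF and θ_g.  Inputs are sampled
  independently across variables and fields — the real joint spatial
  correlation of the drivers is unknown — which makes synthetic regional
  totals more nearly normal (thinner-tailed) than the strongly right-skewed
  real-region distribution.  Passing tests therefore validate the engine's
  mechanics (determinism, linearity, truncation, model routing), not the
  real region's production level, which depends on the unavailable salinity
  raster.
* **Gamma-reference region** — a calibration construction with an
  analytically known production mean: every field uses the full model with
  only θ_g stochastic, so yield is linear in the one random input, never
  truncates, and E[Q] follows from linearity; total area is scaled so E[Q]
  equals a target distribution's mean.  End-to-end mean checks against this
  construction are independent of the engine under test.

## Numerical choices and limitations

* Grid searches use multiples of the step size, so exact generating
  breakpoints on the grid are recovered exactly on noiseless data; ties
  resolve to the smallest candidate.
* Degenerate PDFs (zero SD) short-circuit to their means, making the
  deterministic single-pass pipeline an exact oracle for the Monte Carlo
  engine.
* Sample skewness/kurtosis of a numerically constant vector are reported
  as 0 rather than propagating catastrophic cancellation.
* Lognormal rejection sampling raises after a bounded number of rounds if
  bounds are essentially incompatible with the PDF.
* The full-model polynomial is concave, not monotone, in salinity: below
  the vertex, raising salinity raises predicted yield.  Monotonicity
  guarantees therefore apply to the tolerance path only.
* Yields, areas and volumes are fixed as kg/ha, ha and ML = 10⁶ L
  throughout; converting at other units is the caller's responsibility.
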
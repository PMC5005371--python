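# Methods

## Thermal indices and covariates

CWSI and Ig are computed from the canopy median temperature and the wet
and dry reference medians of the same frame.  Both are dimensionless;
values outside [0, 1] (canopy cooler than the wet or hotter than the dry
reference) are physically possible and are *retained with a warning*
rather than clipped — clipping would bias the regression models
downstream.  The identity `Ig = (1 − CWSI)/CWSI` holds wherever both are
defined and is enforced by property tests.

Vapor pressure deficit follows the FAO-56 form,
`e_s = 0.6108·exp(17.27 T/(T+237.3))`, `VPD = e_s(1 − RH/100)` in kPa.

Percent soil water deficit (PSWD) is stored as a **deficit-positive
fraction**: `(weight_at_field_capacity − weight_actual) /
water_content_at_field_capacity`, where the plant-available water content
at field capacity is 40% of the substrate at 10 kPa matrix potential.
0 means field capacity, 1 means the whole plant-available water is gone,
negative values mean over-saturation.  Published conventions for this
quantity are inconsistent (some report over-saturation as positive); the
deficit-positive fraction is adopted because the magnitudes of quadratic
index-response coefficients of order ±2 are only interpretable on a 0–1
predictor scale.  This is a documented convention, not a claim about any
particular prior usage.

## Emissivity handling

The camera acquires at emission coefficient 1.  Per-surface apparent
emissivities are calibrated as the contact/image temperature quotient on
the kelvin scale — a ratio of temperatures is only physically meaningful
in kelvin — and correction inverts that calibration exactly:
`T_corrected_K = ε · T_apparent_K`.  The round trip
`correct(t_image, estimate(t_contact, t_image)) = t_contact` holds to
machine precision and is tested.  Note these quotients are *apparent*
emissivities in a calibration sense: no background-radiation
compensation is modelled (negligible in a shaded greenhouse).

## Image-processing chain

Per frame: (1) unsharp mask `S = (I − w·G_σ(I))/(1 − w)` with σ = 2 px
and w = 0.9, reflective boundaries — the standard definition of the tool
command those parameters come from; (2) the sharpened image is **clipped
to the radiometric range of the original raster** before histogramming,
exactly as an 8-bit display-scaled conversion would saturate it; without
this, thin-structure overshoot (tens of degrees beyond the measured
range) dominates the histogram span and the intermodes algorithm locks
onto an overshoot mode; (3) intermodes thresholding on the canopy search
region (everything outside the fixed reference rectangles): the 256-bin
histogram is smoothed with (1, 2, 1)/4 until exactly two maxima remain,
the threshold being the midpoint of the mode centers.  Smoothing runs in
exact integer arithmetic, so mode positions carry no floating-point
round-off at any depth, and a two-mode state must persist for 50 further
passes — genuine bimodality persists for hundreds — so transient noise
maxima in unimodal histograms raise `not bimodal` instead of yielding a
spurious threshold.  A scene whose search region spans less than 2 °C
(no plant/background contrast) is rejected outright.  (4) Pixels *below*
the threshold are plant candidates (the heated plates are hotter than any
transpiring canopy); (5) needle-edge removal discards candidates under
the 1-px-dilated mask of Sobel gradient magnitudes exceeding their Otsu
split within the candidate set; (6) medians per region are read from the
**original** raster (masks need no radiometric fidelity; sharpening
distorts radiometry) and emissivity-corrected; reference medians first
drop the upper temperature decile of their rectangle to exclude rims and
shadows.  1–3 replicate images per tree and day are averaged; failed
replicates are skipped with a warning.

The reported `threshold_used` lives on the clipped-sharpened scale the
masks were built from (`threshold_scale="sharpened"`); the canopy's
sharpened median is below it by construction, while the original-scale
median need not be.

## Synthetic scenes

A scene renders the monitoring platform: background at the plate
temperature (40 °C), wet/dry reference rectangles (22/38 °C), a canopy of
needle segments radiating from a 5-px stem axis, an edge band in which
each canopy-adjacent pixel is, with probability `edge_mix_fraction`, a
mixture `α·T_canopy + (1 − α)·T_plate` with `α ~ U(0.2, 0.8)`, and i.i.d.
Gaussian sensor noise.  Needles are drawn 3–5 px wide on a 192×192 frame
so that their interiors remain radiometrically resolved under the σ = 2
unsharp mask, mirroring the enhanced-resolution camera for which a needle
spans several pixels; at 1–2 px width the unsharp overshoot destroys the
canopy histogram mode entirely and no histogram threshold can work.
Ground-truth masks (canopy/wet/dry/edge/background) partition the frame
exactly.  Generators are pure functions of (parameters, seed).

The segmentation-accuracy study draws per-scene noise from
U(0.02, 0.15) °C, bracketing the imaging hardware's thermal resolution
(< 0.08 K), with 30% edge-mixed pixels.  A regime analysis motivated the
range: edge removal strictly improves the canopy median at
sensor-realistic noise, ties around 0.2 °C, and *backfires* by ~0.3 °C,
where rare background noise excursions that fall below the threshold
survive the gradient cut and carry more weight in the smaller mask.
That limitation is inherent to purely local edge filtering and is left
visible rather than patched with connectivity heuristics.

## Synthetic experiment tables

48 trees (6 provenances × 2 treatments × 4) × 17 measuring days, laid on
a calendar of twice-weekly offsets across a 61-day study with a 42-day
treatment window.  Meteorology is sampled uniformly within the printed
measuring-day envelope (T 20.4–37.1 °C, RH 29–66%, radiation
24–234 W/m²) as a day mean plus small within-day jitter per tree, with
VPD computed from T and RH; a random within-day measurement order is
recorded.  PSWD follows per-treatment target trajectories (identical
before the divergence at measuring day 4, the drought arm drying to
~0.95 and both relaxing after re-saturation at day 14) plus a tree-level
jitter offset.  The response is `Xβ + b_tree + ε` with
`b ~ N(0, σ₀²)`, `ε ~ N(0, σ_ε²)`, built on **uncentered** covariates
(centering belongs to the modelling stage); for Ig the linear structure
lives on the square-root scale and the stored index is the squared linear
response.  Default coefficients are the headline deficit-response values
on the fraction scale (PSWD −2.49, PSWD² +1.61, VPD 0.044, radiation
0.00032 for CWSI) with σ₀ = 0.05, σ_ε = 0.08; the treatment family
defaults to the stress-period main effects (treatment −0.23, scaled time
+0.42/−0.42, …) with covariate×treatment interactions at zero, because
those printed interaction values presuppose mean-centered covariates and
would distort the marginal treatment gap when applied to uncentered ones.

## Mixed-model engine

Random-intercept Gaussian LMM fitted by profiled likelihood: for a
variance ratio θ = σ₀²/σ_ε² (and optional variance-function parameter),
the per-tree marginal covariance is σ_ε²(W + θ·11') with diagonal W, so
fixed effects and the residual scale have closed-form GLS solutions via
group-wise Woodbury identities; the optimizer searches only over log θ
(bounded in [−18, 10], absolute tolerance 1e-8) or, with a variance
function, over (log θ, δ) by Nelder–Mead.  Supported variance functions:
identity; per-treatment residual variances (δ = log SD ratio of the
drought stratum); and a power of the fitted mean, iterated three times
on the fitted values.  ML is used wherever models are compared (AIC,
covariate-set selection, drop1); REML for the reported fit.  AIC counts
all estimated parameters (fixed effects + two variance components + any
variance-function parameter).  The implementation agrees with an
independent mixed-model implementation to ~1e-5 on coefficients and
log-likelihood in the identity-variance case, collapses onto OLS to 1e-6
when σ₀ = 0, and is invariant (log-likelihood to 1e-6) under re-centering
of covariates.

Marginal/conditional R² use the Gaussian variance-partitioning form:
`var(Xβ̂) / (var(Xβ̂) + σ̂₀² + σ̂_ε²)`, with σ̂₀² added to the numerator
for the conditional version; under non-identity variance functions the
mean implied residual variance enters the denominator.

## Contrast and selection procedures

Covariate-set selection fits the {T + RH} and {VPD} variants under ML and
keeps the lower AIC, ties going to VPD (fewer parameters).
Simplification is backward single-term deletion under ML-AIC, respecting
marginality (an interaction or polynomial keeps its parents), with a full
deletion log.  Provenance scenario contrasts re-center PSWD at the
scenario value (0, 0.5, 1.0), refit, and z-test all 15 provenance pairs
on the main-effect dummies with BH-FDR adjustment; at the re-centered
origin the dummies measure provenance differences at that deficit.
Curvature tests are joint 2-df Wald tests on provenance-pair differences
of the linear and quadratic interaction coefficients, BH-FDR adjusted.
Pairwise tests use normal reference distributions from the fitted
coefficient covariance throughout; one coherent procedure (z-contrasts +
BH-FDR) is used rather than mixing studentized-range and FDR logic, with
FDR families defined per contrast table.  The provenance reference level
is alphabetically first; it is recorded in the output column names.

The treatment family codes drought = 0, control = 1; time is days since
the study start divided by the 42-day treatment window, then centered,
entering linearly and quadratically.  `treatment_effect_reduction`
reports `100·(1 − |β_recovery|/|β_stress|)` and its value rounded to the
nearest ten percent.  Response magnitudes pair every drought tree with
every control tree *within* provenance (the only pairing under which
provenances remain comparable afterwards) on window means over ≥ 3
measuring days, followed by Kruskal–Wallis (tie-corrected) and Dunn's
pairwise z-tests with BH-FDR.

## Validation studies (pinetherm.studies)

The same routines back the acceptance tests and `scripts/acceptance.py`:

* segmentation recovery: 100 scenes of the accuracy suite; fraction of
  canopy medians within 0.3 °C of truth, and paired MAE with/without edge
  removal over 50 scenes;
* CI coverage: 200 replicates of the 48 × 17 design with the headline
  coefficients; Wald 95% intervals for the PSWD linear and quadratic
  terms;
* contrast calibration: 500 complete-null simulations at a 24-tree ×
  8-day design (calibration is size-free; the smaller design keeps the
  study fast); per-contrast rejection rates of the FDR-adjusted scenario
  and curvature procedures, with raw-p rates as a sanity check;
* Kruskal–Wallis null: 2,000 simulations of 4 × 10 null groups against
  the χ²₃ reference (Kolmogorov distance).

## Known limitations

* The edge-removal step degrades above ~0.2 °C sensor noise (see above).
* The synthetic scenes emulate geometry, mixed pixels and sensor noise,
  not radiative transfer, reflections, or leaf energy balance; passing
  recovery tests demonstrates the correctness of the processing chain,
  not the field accuracy of thermography.
* The synthetic meteorology is uniform within the printed envelope and
  carries no diurnal or autocorrelation structure; PSWD trajectories are
  targets plus tree offsets, not a water-balance model.
* Random slopes and temporal autocorrelation are out of scope (random
  intercepts only), as is any real-data coefficient reproduction — raw
  observations for this experimental design are not publicly deposited,
  so all quantitative validation is parameter recovery on synthetic data.
* The variance-function classes are limited to per-treatment variances
  and a power of the fitted mean, the two standard remedies for the
  heteroscedasticity patterns these indices show.
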
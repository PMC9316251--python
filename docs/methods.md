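# Methods

This note documents the models, conventions and numerical choices behind
`torsoshape`, and what the synthetic testbed does and does not establish.

## Synthetic cohort model

Each participant is generated from four independent standard-normal latent
factors: overall adiposity `A`, central fat placement `C`, a large-scale
torso-shape factor `s_L`, and a small-scale shape factor `s_S`. A config
switch (`latent_correlation`) correlates `A` and `C` to stress collinearity
handling; the default is independence.

**Surface family.** The torso is a generalized cylinder whose cross-section
at height z is a superellipse `|x/a(z)|^p + |y/b(z)|^p = 1` (default
exponent p = 2.5) multiplied by cosine harmonics:

```
r(θ, z) = r_se(θ; a(z), b(z), p) · (1 + Σ_k c_k cos(kθ + φ_k)),  k = 2..8
```

Semi-axes are pchip-interpolated through six stations (hip, stomach,
waist, chest/xiphoid, shoulder, neck); `A` and `C` scale the stomach/waist
axes, and a height-scaled anterior centre offset (the belly) makes the
front/back disambiguation of the alignment well posed. `s_L` loads on the
k = 2 harmonic amplitude, `s_S` on k = 5–8; harmonic phases are fixed near
zero (with small per-subject jitter) so the shape features remain linear in
the latent factors — with uniformly random phases the conditional mean of
every Fourier coefficient would be zero and no linear model could recover
the factors. This family was chosen because girth, area, volume and
surface area all have cheap quadrature oracles, and because the two shape
factors act at separable angular scales.

**Dependent variables.**

```
fat%  = 21.02 + 6.0·z(WHT.5R) + 3.5·s_L + ε,      ε ~ N(0, σ_fat)
TPFR  = 1.57 + 0.12·C + 0.13·s_S + ε′,            ε′ ~ N(0, σ_tpfr)
```

`z(WHT.5R)` standardizes the participant's true waist-girth/√height using
population statistics computed once per configuration from an internal
fixed-seed latent sample. The residual SDs default to the values that make
the marginal SDs equal the configured cohort targets (7.82 fat
percentage points, 0.22 for TPFR), so the cohort's marginal distributions
are calibrated by construction; draws outside physical ranges are rejected
and the noise redrawn (bounded retries). Body mass combines a
height-scaled lean mass with the fat fraction; trunk and per-limb fat
masses split total fat according to the drawn TPFR (8% of fat is assigned
to head/neck and is invisible to the trunk/limb accounting).

**Scans.** One scan per subject: points sampled uniformly in (θ, z) on the
torso surface plus four tapered-cylinder limb proxies (thigh-girth plateau
near the top of the leg; bicep bulge below the xiphoid level so both
maximum girths are observable), with isotropic Gaussian noise (default
σ = 2 mm) and a noise-free landmark sidecar. The default budget is 200 000
points per scan, which leaves ≈300 points in each 2 mm torso band — dense
enough that the 30° angular-gap guard on contour smoothing essentially
never trips (at ≈180 points/band the worst-gap tail made roughly one band
in 10⁴ fail, i.e. a failure per few hundred subjects). Large cohorts are
processed streamingly — each scan is rendered, reduced to features, and
discarded — so memory stays flat in cohort size. Arms are offset laterally well clear of the torso (a
downward-V posture proxy). θ-uniform sampling is not arc-length-uniform;
the small induced density variation is irrelevant to the contour fits.

Triplicate-scan median selection, posture/clothing artifacts and female
morphology are out of scope.

## Geometry conventions

* Xiphoid at exactly 60% of the buttock→neck distance (the ±1.5% reported
  for that landmark is population spread, not an applied tolerance).
* Alignment is entirely data-driven, hence rigid-motion invariant: the
  torso slab is isolated with a *scale-free radial-gap filter* (a decisive
  relative gap in the distribution of horizontal distances from the median
  axis separates detached arm clouds); the principal axis of the
  horizontal spread maps to +y (skipped for near-isotropic sections); +x
  is oriented toward the greater mean offset at stomach level; the origin
  is the midpoint of the 1%/99% x- and y-quantiles at xiphoid level (the
  xiphoid/spinous centre-line proxy — extreme quantiles of a convex
  section are densely sampled and therefore stable).
* 25 bands of 2 mm at centres (i+0.5)/25 of the torso length, i = 0..24
  (no degenerate end bands).
* Centroid size is computed jointly over all 25 bands (per-band scaling
  would discard the waist-to-hip taper; a per-band variant exists for
  sensitivity analysis). By default each band is first resampled to 128
  uniform semilandmarks so the measure is independent of sampling density;
  the raw sum-over-points definition is available (`resample=False`) and
  differs only through sampling, not geometry. With fixed 2 mm bands the
  full-chain scale invariance holds at contour/feature level (a magnified
  scan's slabs contain different raw points), and is tested there.

## Shape features

* Band → polar radius about the band centroid → cubic smoothing spline
  with the penalty chosen by generalized cross-validation
  (`scipy.interpolate.make_smoothing_spline`); the data are wrap-padded by
  ±90° so the fit is continuous across the 0/2π seam (scipy's FITPACK
  periodic mode proved unreliable on exactly periodic inputs). An angular
  gap > 30° raises — a broken contour cannot be closed by smoothing.
* The contour is the complex sequence z_j = x_j + i·y_j at 128 uniform
  angles; "lowest 10 coefficients" means the 10 smallest-|frequency| DFT
  terms, ordered (0, +1, −1, +2, −2, +3, −3, +4, −4, +5). Negative
  frequencies are required to represent ellipses; the DC term carries the
  band-centroid offset (the belly line), which is genuine shape after
  scaling. 25 × 10 complex = 500 real features, interleaved re/im,
  band-major.
* The PCA basis is fit once on a reference cohort of 400 synthetic
  participants whose features come from noise-free analytic contours (the
  basis plays the role of externally derived eigenvectors, so a separate
  seed guarantees the study cohort is projected onto a basis from
  different data). Components carry a deterministic sign convention
  (largest-|loading| entry positive, near-ties broken by lowest index).
  Bases serialize to JSON with a schema version.

## Body-composition emulation

ADP: volume readings are true body volume (mass over the density implied
by the true fat fraction) plus N(0, 0.05 L) noise; if the first two differ
by more than 150 mL a third is drawn and the closest pair is averaged
(ties → earlier pair). Density equations (fat% = (c₁/D − c₂)·100):
Siri (4.95, 4.50), Schutte (4.374, 3.928), Brozek (4.570, 4.142); the
equation is an explicit tag rather than auto-selected, because no
quantitative rule for "extremely lean or obese" is available. BIA: two
repeats of the five segmental fat masses with N(0, 0.1 kg) noise,
averaged; TPFR = trunk fat / Σ(limb fats). With both noise SDs at zero the
measurements equal the truth exactly. Thoracic gas volume and raw
impedance are not modelled.

## Statistical engine

* **Stepwise-AIC.** Start from the 10 main effects. Forward passes add the
  pairwise-interaction candidate that most lowers the AIC (any
  improvement counts); backward passes remove a term only if removal
  lowers the AIC by ≥ 0.01 (hysteresis, preventing add/remove cycles); a
  visited-state guard makes termination deterministic; at least one term
  is always retained. "Added if they increased the AIC" in the original
  protocol description is read as *improved the criterion*, i.e. AIC
  minimization, the universal stepwise convention. No polynomial or
  ≥3-way terms. Interaction columns are products of centred, scaled main
  effects, which makes the AIC path invariant under affine rescaling of
  predictors. Main effects may be dropped while their interaction remains
  (no marginality constraint by default; `hierarchy=True` enforces one).
  AIC = n·ln(RSS/n) + 2(k+1), which matches Gaussian-likelihood AIC up to
  a constant shared by all models of the same n.
* **Subset search.** All C(10,5) = 252 subsets of 5 shape parameters are
  fit with the full stepwise procedure and scored by training MSE;
  ties break lexicographically.
* **Evaluation.** adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) with p = number of
  selected terms; 10-fold CV uses a seeded shuffled partition and refits
  coefficients per fold with the term structure frozen (re-selection per
  fold is available as `cross_validate_reselect` for honesty analyses;
  interaction columns use full-data centring constants, a deliberate,
  documented simplification). Final coefficients and p-values come from a
  statsmodels OLS refit.
* **Relative weights.** Johnson's method: SVD X = UΣVᵀ of the
  standardized design, orthonormal approximation Z = UVᵀ, loadings
  Λ = VΣVᵀ, weights ε = (Λ∘Λ)(β∘β) with β = Zᵀy (correlation metric).
  Raw weights sum to R² (asserted to 1e−6); reported as percentages.
  Rank-deficient designs raise.

## Report conventions

Model groups: shape-containing = {anthro_shape, shape_sa, shape_vol},
size-only = {anthro_sa, anthro_vol}, shape-only separate. Every printed
aggregate (group mean adjusted R², CV-RMSE inflation 100·(cv/train − 1))
is recomputed from the report's rows at render time; rounding (R² to 4 dp,
RMSE 2–3 dp, inflation 1 dp) happens only at presentation. Top-weight
tables keep the three largest significant (p < 0.05) terms.

## Problem sizes and determinism

Default study sizes: reference basis n = 400 (analytic features), study
cohorts n = 93 (protocol-sized) to n = 500 (recovery tests in the suite),
calibration checks n = 1000 (truth only). The acceptance script uses
n = 200 for the end-to-end comparison and n = 1000 for calibration. All
randomness flows from explicit seeds through spawned `SeedSequence`
streams, so every cohort, fit and CV partition is reproducible.

## What passing tests show — and what they don't

The synthetic generator plants linear, phase-locked shape signals in a
noise-free-landmark, occlusion-free scan geometry. Passing the suite shows
the pipeline recovers exactly the structure it is designed to carry:
large-scale shape informs fat amount, small-scale shape informs fat
distribution, and shape-augmented models beat size-only models with the
larger gain for distribution. It does not show that real torsos satisfy
the superellipse-plus-harmonics family, that real landmark detection is
noise-free, that BIA/ADP errors are Gaussian, or that the published
eigenvectors resemble the synthetic basis. Limb "volumes" are measured
over each limb's observable band window (legs below the buttock; arms
below the xiphoid), a consistent but window-limited convention, so they
are proportional to, not equal to, full-limb volumes.

## Known limitations

* The allometric exponents used in the original protocol are not public;
  β defaults to 1 for all girths/lengths (and height-proportional
  normalization for volumes/areas), with per-measure overrides in config.
* Near-circular cross-sections make the principal-axis rotation undefined;
  the alignment skips rotation when the axis ratio is < 1.05, which is
  correct for the synthetic family but would need a landmark-based rule
  for real scans.
* The gap-filter that isolates arm clouds assumes laterally detached
  limbs; pressed-to-torso arms would require labelled segmentation.
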
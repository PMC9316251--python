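# torsoshape

Torso-shape descriptors from 3D body scans, and regression models that test
whether shape improves the prediction of body-fat **amount** (body-fat %,
as measured by air-displacement plethysmography) and body-fat
**distribution** (the trunk:peripheral fat ratio, TPFR, from segmental
bioelectrical impedance analysis).

The package is written for researchers in anthropometrics and body
composition who want a reproducible, fully synthetic testbed for the
scan-to-model pipeline: every stage — scan rendering, torso segmentation,
Fourier/PCA shape extraction, body-composition emulation, and the
model-comparison statistics — runs from generated data, so no scanner or
participant data is required.

## The method

1. **Torso geometry.** A scan is segmented between the buttock landmark and
   the xiphoid process (placed at 60% of the buttock-to-neck distance),
   aligned to an anatomical frame (x sagittal, y transverse, z
   longitudinal), and cut into 25 bands of 2 mm at uniform intervals.
   Profiles are jointly rescaled by centroid size
   `CS = sqrt(sum_i |p_i - p̄|²)` to remove scale.
2. **Shape parameters.** Each band contour is smoothed with a cubic
   smoothing spline on r(θ) (GCV penalty), resampled at M = 128 uniform
   angles, and Fourier-transformed as z_j = x_j + i·y_j. The 10 lowest
   |frequency| complex coefficients per band (ordered 0, ±1, ±2, ±3, ±4,
   +5) give 250 complex = 500 real features per torso. A frozen
   10-component PCA basis — fit once on a separate synthetic reference
   cohort — yields shape parameters PC1..PC10.
3. **Size parameters.** Girths (waist = torso minimum, stomach, hip,
   chest), torso length, WHT.5R = waist/√height, limb girths, and
   volumes/surface areas by band integration; all height-normalized by
   allometric scaling y/H^β.
4. **Models.** Six 10-parameter model types per dependent (shape-only, two
   anthropometrics+size sets, and three shape+size combinations whose best
   5-of-10 PC subset is found by exhaustive search over all 252 subsets).
   Each model is fit by forward/backward stepwise selection on the AIC over
   pairwise interaction candidates, then judged by adjusted R², RMSE,
   seeded 10-fold cross-validated RMSE, and Johnson relative weights.

## Worked example

```python
import torsoshape as ts

config = ts.GeneratorConfig(n_subjects=200, seed=7)
study = ts.run_study(config)                # scans -> PCs + size parameters
comp = ts.ModelComparison(study)
shape = comp.fit_one("anthro_shape", "tpfr", seed=7)
size = comp.fit_one("anthro_vol", "tpfr", seed=7)
print(f"shape+size adj R2 {shape.adj_r2:.3f} ({shape.n_terms} terms), "
      f"subset {shape.shape_subset}")
print(f"size-only  adj R2 {size.adj_r2:.3f} ({size.n_terms} terms)")
```

Output from this exact snippet:

```
shape+size adj R2 0.595 (13 terms), subset ('PC2', 'PC3', 'PC5', 'PC6', 'PC8')
size-only  adj R2 0.278 (10 terms)
```

Read: adding five shape parameters to the five size measures roughly
doubles the adjusted R² for fat distribution (0.28 → 0.60) on this
synthetic cohort, because the generator plants a small-scale shape signal
(high angular frequencies) that size measures cannot see. `StepwiseResults`
objects also expose `summary()`, `cross_validate()` and
`relative_weights()`.

A CLI mirrors the pipeline: `torsoshape simulate | extract | features |
fit | report` (see `torsoshape --help`).

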
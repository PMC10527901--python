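# Methods

## Measurement model

One observation is a pair of mean-RGB triplets extracted from a photograph
of an oil blend in a glass test tube against white paper: the oil region
(`sample`) and the empty-tube region directly above the liquid (`blank`).
The blank is the method's white reference: it sees the same illumination,
camera gain and exposure as the sample, so lighting effects that act on
both can be cancelled by comparing them.

The quantity modeled is the w/w soybean-oil fraction of the blend,
*y* ∈ [0, 1], observed on an inclusive uniform grid of 41 levels (2.5%
steps) by default.

## Synthetic data generator

The generator emulates this measurement with a Beer–Lambert-style
transmittance law. Each pure oil is characterised by a non-negative
per-channel optical density; the density of a blend is linear in the
fraction, and per channel *c*:

    blank_c  = g · gain_c · white_level + ε_c
    sample_c = g · gain_c · white_level · exp(−(f·a1_c + (1−f)·a2_c)) + ε'_c

with `g = exp(N(0, σ_jitter))` a per-shot brightness multiplier **shared by
the sample and its blank** (the lightness effect the corrections target),
`gain` a per-condition channel gain (device × illumination color balance),
and independent additive pixel noise `ε ~ N(0, σ_noise)` on the 0–255
scale. With `clip_raw=True` (default) channels are clipped to [0, 255] for
8-bit realism; tests that need exactly log-linear data switch clipping off.

Why transmittance mixing: it makes `log(sample/blank)` exactly linear in
the fraction, and the raw channels nearly linear over moderate densities —
the regime in which a linear calibration is the right model. A useful and
non-obvious numerical fact: with three channels of *distinct* densities,
the span of the three exponentials (plus intercept) cancels the curvature
through third order, so a noiseless 41-point series is fit by OLS to RMSE
≈ 1e−9 in fraction units even at densities of order 0.1–1.

### Default parameters

All generator numbers are package configuration, not measurements, and can
be overridden per call or via the experiment config.

| parameter | default | rationale |
|---|---|---|
| white_level | 255 | white paper at the top of the capture scale under unit gains |
| SO absorbance (R,G,B) | 0.05, 0.03, 0.14 | refined soybean oil: pale yellow (mostly blue absorption) |
| EVOO absorbance | 0.32, 0.10, 0.85 | yellow-green; green is the most transmitted channel |
| AVO absorbance | 0.48, 0.24, 1.05 | the most intensely colored of the three oils |
| channel gains | 0.83–0.95 per condition | four distinct device × lighting color balances; kept below 1 so blanks stay under 8-bit saturation even with positive lightness jitter |
| lightness jitter σ | 0.03 (artificial light), 0.05 (natural) | natural light varies more shot-to-shot |
| pixel noise σ | 2.0 (SG), 2.5 (SM) | ~1% of full scale; the cheaper camera is noisier |

The primary condition is SG-IA; SM-IN, SM-IA and SG-IN are transfer
targets. What the generator does **not** emulate: camera gamma and
white-balance algorithms, JPEG compression, tube geometry/reflections, and
oil aging. Passing tests therefore demonstrate that the pipeline recovers
what this optical model encodes — multiplicative/additive lighting
perturbations and moderate noise — not that any physical camera is
calibrated.

## Corrections

All corrections are computed on full RGB before descriptor selection, and
corrected values are never clipped (they are model inputs, not colors).

- **illuminance**: divide sample RGB by the blank's theoretical illuminance
  `Y = −0.32466·R + 1.57837·G − 0.73191·B` (a CIE-Y-style luminance
  approximation evaluated with exactly these coefficients). Invariant to a
  common positive scaling of sample and blank — precisely the per-shot
  lightness multiplier. `Y ≤ ε` (default ε = 1e−6) raises a
  degenerate-blank error naming the sample: a non-positive illuminance
  means the blank patch is not a plausible white reference, so a signed
  check is used rather than an absolute value.
- **blanks difference**: `sample − (own_blank − primary_mean_blank)`;
  invariant to additive offsets shared by sample and blank.
- **blanks ratio**: `sample · primary_mean_blank / own_blank`; invariant to
  per-channel gains shared by sample and blank; near-zero blank channels
  raise a degenerate-blank error.

The **primary mean blank** is the channel-wise mean over the blanks of the
primary series. By default all 41 samples contribute; a
`blank_scope="calibration"` option restricts it to the ~33 calibration
rows. (The published description says the 41 calibration samples although
the calibration split is 80%; both readings are supported and the default
follows the all-41 wording.)

## Calibration and validation

- **Split**: default "systematic" — sort by fraction, hold out every 5th
  sample starting at position 2, giving 33/8 on the 41-grid with both
  endpoints in calibration; a seeded "random" scheme is available.
- **Fit**: OLS with intercept (`numpy.linalg.lstsq`); rank-deficient
  designs raise; n ≥ p + 1 is required (the minimum is exact
  interpolation). Tests cross-check coefficients against an explicit
  normal-equations solve at 1e−10.
- **R²** for observed-vs-predicted comparisons is the squared Pearson
  correlation, not 1 − SSres/SStot. The two coincide on OLS training data;
  on transfer data only the correlation form can report R² ≈ 0.96 next to
  RMSE near 0.8 on a 0–1 response — which is exactly the pattern the
  published transfer tables show, and the r²m statistic is what then flags
  the bias.
- **r²m** = r²·(1 − √|r² − r₀²|), with r₀² from the through-origin fit of
  predicted on observed (slope k = Σ(obs·pred)/Σ(obs²)); a reverse-direction
  variant is exposed. The value is clamped at 0 (strongly incongruent
  predictions drive the raw expression negative; the published tables print
  0 in those cells). Note a structural property: exactly proportional
  predictions (pred = c·obs, no scatter, no offset) fit the through-origin
  line perfectly and keep r²m = 1 — r²m penalises additive bias and
  slope-plus-scatter combinations, not a pure noiseless gain. r²m ≥ 0.5 is
  reported as "congruent". (The source description of the threshold is
  self-contradictory — it once says values *below* 0.5 are acceptable and
  elsewhere reads > 0.5 as good; the conventional ≥ 0.5-congruent reading
  is implemented.)
- **y-randomization**: 100 seeded response permutations by default (the
  count is a package choice; the original count is unpublished); in-sample
  RMSE and R² of each refit are averaged. On a 33-point evenly spaced grid
  the expected randomized R² is p/(n−1) ≈ 0.094 for p = 3 and the expected
  randomized RMSE is sd(y)·√((n−p−1)/n) ≈ 0.28 — both are asserted in
  tests. The summary R²p = √(R²cal)·√(R²cal − mean R²rand), clamped at 0;
  this form reproduces the published R²p cells from their printed inputs.
- **Cross-validation**: leave-one-out by default (the original flavor is
  unpublished); seeded k-fold available.
- Predictions are never clipped to [0, 1]; published transfer RMSEs above 1
  show the original statistics were not clipped either.

## Calibration transfer

A primary-condition model is applied to secondary series unchanged: each
secondary sample is corrected using the **model's stored primary mean
blank** together with the sample's own blank, never a blank mean recomputed
from secondary data (that would be recalibration). The full grid — 4
descriptor sets × 4 corrections × 3 secondary conditions — yields a
48-row transfer report with RMSE, R², r²m and a congruence flag. All 41
secondary samples are scored (whether the original used a subset is
unpublished).

## Reproducibility and numerical choices

- Every stochastic step takes a seed; the experiment runner derives
  per-stage seeds from one master seed by hashing stable stage names
  (CRC-32 into a `SeedSequence`), so adding a stage does not shift
  existing streams. Identical configs reproduce byte-identical report CSVs.
- Division guards use ε = 1e−6 on the 0–255 scale.
- Dataset rows enforce the fraction ∈ [0, 1] invariant but deliberately do
  not enforce a [0, 255] channel range: unclipped rendering and corrected
  values may leave it by design.
- The acceptance script uses the default study conditions: 41 levels, one
  replicate, default noise; the permutation target uses the 33-point grid
  with 100 permutations. These sizes match the study design itself, so no
  scaling down was needed.

## Known limitations

- The generator's flat-patch optics ignore spatial structure; `extract`
  works on real rasters, but no tube-detection is provided (ROI coordinates
  are user input).
- Absorbances and gains are plausibility presets, not measured oil spectra;
  absolute RMSE levels on synthetic data should not be read as instrument
  performance.
- The correlation-based R² can stay high under severe transfer bias; read
  it together with RMSE and r²m, as the reports do.
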
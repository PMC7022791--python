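# Methods

## Segmentation model

A tissue crop is assumed to be a two-phase scene — pale fat on a dark
red lean matrix — observed through a smooth multiplicative illumination
field and additive sensor noise. Two binarization paths are
implemented.

**Unfiltered.** Grayscale (Rec. 601 luma, 0.299 R + 0.587 G + 0.114 B,
rounded half-up) followed by a fixed manual threshold at gray level
175, with the ≥ convention (a pixel exactly at the threshold is fat).
This is correct whenever fat and lean luma stay on opposite sides of
175, and degrades exactly where shading pushes fat luma below it.

**High-pass filtered.** The canonical high-pass flattening workflow,
reconstructed with explicit conventions because the commercial filter
kernels are unpublished:

1. *High-pass layer* = grayscale − Gaussian blur + 128, clipped to
   [0, 255]. The blur uses σ = radius/3 with the kernel truncated at
   3σ and edge replication at the borders (a zero-padding border would
   create a dark vignette the filter would then "correct"). The
   radius-to-σ mapping is a fixed, documented convention.
2. *Overlay blend* of the high-pass layer onto the grayscale original:
   with a, b ∈ [0, 1], result = 2ab where a < 0.5, else
   1 − 2(1−a)(1−b). Overlay is neutral at mid-gray, so smooth regions
   pass through unchanged while edges are locally contrast-stretched.
3. Threshold at 150, same ≥ convention.

Filtering acts on the grayscale image rather than per RGB channel:
binarization follows immediately, so only luma can matter. The blend
operator is isolated in one function (`overlay_blend`) so alternatives
(linear light, plain sum) can be substituted without touching the
paths.

Radii of 25 and 50 px are exposed as the `hp25`/`hp50` method presets;
structures larger than the radius are attenuated by the filter, so the
radius bounds the fat-cluster size that survives unchanged.

## Sandbox estimator

The fat phase carries a uniform counting measure (one unit per fat
pixel; a config switch analyzes the muscle phase instead). For center
x on the set and radius r, M(r) counts set pixels with pixel-center
Euclidean distance ≤ r. The order-q dimension is the OLS slope of

y_j = (1/(q−1)) · ln ⟨(M_i(r_j)/M₀)^(q−1)⟩_i    against    x_j = ln(r_j / L),

with the average over centers taken before the logarithm (moment
form); q = 1 uses the entropy form y_j = ⟨ln(M_i(r_j)/M₀)⟩_i rather
than q = 1 ± ε, which would introduce an arbitrary ε.

Numerical choices, with defaults:

* **Centers:** 1000, drawn uniformly *with replacement* from set
  pixels at distance ≥ r_max from every border, so every disc fits in
  the image and no count is edge-truncated. The alternative —
  per-radius center sets — would break comparability across radii.
  With 1000 centers, two independent draws move each dimension of the
  level-5 carpet by < 0.03.
* **Radii:** 12 geometrically spaced values in [5, L/4] px; 5 px keeps
  discs above pixel discreteness, L/4 keeps them below the crop scale
  while leaving an eligible center region.
* **Counting:** FFT convolution of the mask with the binary disc
  kernel, rounded back to integers; counts are bounded far below the
  float64 mantissa, so the result is exact, and a brute-force
  per-pixel oracle test confirms exact agreement on random masks.
* **Fit:** ordinary least squares over *all* configured radii. No
  automatic scaling-range selection is performed — that is a research
  choice the estimator should not make silently; instead the slope
  standard error and R² are attached to every estimate so a user can
  re-fit on a sub-range. A standard error below 0.1 is the
  conventional suitability bound for such estimates; all benchmark and
  fixture estimates here sit well below it (worst ≈ 0.05).
* **Degenerate inputs:** fewer than `min_support_px` (default 100) set
  pixels, or no set pixel far enough from the border, raise explicit
  errors naming the remedy. Masses are guaranteed ≥ 1 because centers
  lie on the set.

Estimator bias worth knowing about: on the level-5 Sierpinski carpet
(243 px) the recovered D₀ is ≈ 1.84 against the analytic 1.893 — the
finite scaling range and lacunarity oscillations of the carpet bias
the slope slightly low. The filled square reads 1.994 and a 64-px line
0.97. These recoveries, not exact equality, are what the acceptance
checks assert (±0.1 for D₀, ±0.15 for D₁/D₂ on the carpet).

## Synthetic slice generator

The generator emulates the features of slice photographs that matter
to this pipeline, with ground truth no photograph can provide:

* **Marbling:** random-walk polyline streaks (step 3 px, angular
  jitter SD 0.25 rad, length L/8–L/2) dilated to widths 1–4 px, plus
  elliptical fat clusters with semi-axes L/64–L/20. Streaks are drawn
  from a re-seeded stream so the first k streaks are identical
  regardless of the total count; the mask is therefore monotone in the
  streak count and the fat fraction can be calibrated by integer
  bisection (≤ 20 mask draws, target tolerance 0.02, hard failure
  beyond 0.05).
* **Illumination:** a multiplicative field 1 + A·s(x, y), where s is a
  sum of three random plane-wave harmonics with wavelengths 2–4 × the
  stated correlation scale, centred and rescaled so the mean is
  exactly 1 and the peak deviation exactly A. Multiplicative (not
  additive) shading matches physical vignetting and is what a
  high-pass filter removes; the scale must exceed the filter radius
  for removal to be possible.
* **Colors and noise:** lean (120, 30, 30) and fat (250, 245, 230) —
  lumas ≈ 57 and ≈ 245, straddling both thresholds with margin — with
  optional per-pixel Gaussian noise.

The study conditions used by the robustness tests and the acceptance
script are 512-px slices, 20 % fat, shading amplitude 0.3 at 128-px
scale, noise SD 3, 20 slices; the class fixture in `analysis/` uses
four classes at 10/15/20/30 % fat, six slices each, with ±5 % relative
jitter on the target and ±2 on the cluster count to create
within-class dispersion.

What the generator does *not* emulate: photorealistic tissue texture,
camera optics, JPEG artifacts, specular highlights, or the true
morphology distribution of any ham designation. Passing tests
demonstrate that the pipeline recovers known structure under
controlled heterogeneity — not that it measures real hams accurately;
no public image set exists to test that claim.

## What the comparison shows

Under the study conditions, shading pushes part of the fat phase below
the unfiltered threshold (mean accuracy ≈ 99.8 %), while the 25-px
high-pass path recovers the ground-truth mask essentially exactly; the
pooled IQR of D₀ across same-class slices is correspondingly no wider
under `hp25` than unfiltered. Note that the filtered path's advantage
lives in the *within-class* dispersion: in the four-class analysis the
pooled-over-class IQR is dominated by the between-class fat-fraction
spread, and small inversions for D₁/D₂ there reflect class spread,
not filtering.

## Reporting conventions

Per-class/per-method tables report the mean and the across-sample
standard error SD/√n (sample SD, ddof = 1); the regression standard
error of each individual estimate is a different quantity and is never
mixed in. Quartiles and IQRs use inclusive linear interpolation (the
SPSS-compatible convention); five-number summaries require n ≥ 5. No
significance testing is performed — the module is descriptive by
design.

## Determinism

All randomness flows from explicit integer seeds: generator parameters
plus seed give bit-identical rasters, and a configured batch rerun with
the same seed reproduces every CSV/JSON output byte-for-byte (the run
manifest differs only in its wall-clock timestamp, and records a
canonical config hash that is stable under key reordering).

## Problem sizes

The test suite and acceptance script run on 512-px crops (the
pipeline's native size), a 243-px carpet, and batches of 20–24 slices
— sizes chosen so the full validation completes in a few minutes on
one CPU while keeping every disc-radius decade the estimator uses.
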
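# hamfrac

Sandbox multifractal analysis of fat marbling in tissue-slice images,
with high-pass illumination correction.

## The problem

Visible intramuscular fat — marbling — is a central quality trait of
cured meats such as dry-cured Iberian ham. Photographs of hand-cut
slices can quantify it, but they are heterogeneous in color and
luminosity: different muscles, different lighting across the slice.
A segmentation that thresholds raw gray levels confuses that shading
with tissue, and the error propagates into any texture statistic
computed from the mask.

`hamfrac` implements and compares two segmentation paths on square
512 × 512 px crops, then characterizes the fat phase with generalized
(Rényi) dimensions:

* **unfiltered** — Rec. 601 grayscale, manual threshold at 175
  (pale fat above, dark red lean below);
* **high-pass filtered** — a high-pass layer (original − Gaussian blur
  at radius 25 or 50 px, re-centred at mid-gray), superimposed on the
  grayscale original with an Overlay blend, thresholded at 150. The
  filter removes slowly varying illumination so the threshold acts on
  local contrast.

The fat mask's structure is summarized by the sandbox method: discs of
growing radius *r* are centred on random fat pixels, the fat mass
*M(r)* inside each disc is counted, and the generalized dimension of
order *q* is the log-log slope

D_q = slope of (1/(q−1)) · ln ⟨(M(r)/M₀)^(q−1)⟩ versus ln(r/L),

with the entropy (L'Hôpital) form ⟨ln M(r)/M₀⟩ at q = 1. D₀ is the
capacity (box-counting) dimension of the support, D₁ the information
dimension, D₂ the correlation dimension; D₀ ≥ D₁ ≥ D₂ always.
Each slope is an ordinary least-squares fit over 12 geometrically
spaced radii and is reported with its regression standard error and R².

Because no public image set exists for this problem, the package ships
a first-class synthetic generator: marbled slices with known
ground-truth fat masks, controllable fat fraction, streak/cluster
morphology, multiplicative illumination heterogeneity and sensor
noise — plus benchmark fractals (Sierpinski carpet, filled square,
line) whose dimensions are known analytically. Every downstream stage
is validated against those oracles.

## Worked example

```python
from hamfrac import (SandboxConfig, SliceParams, analyze_mask, fat_fraction,
                     make_slice, run_method)

# a 512-px synthetic slice: 20 % fat, ±30 % multiplicative shading
params = SliceParams(fat_fraction_target=0.20, illumination_amplitude=0.3,
                     illumination_scale_px=128.0, noise_sd=3.0, seed=1)
image, truth = make_slice(params)

for method in ("unfiltered", "hp25"):
    mask = run_method(image, method)
    print(f"{method}: accuracy {(mask == truth).mean():.4f}, "
          f"fat fraction {fat_fraction(mask):.4f}")

analysis = analyze_mask(run_method(image, "hp25"), SandboxConfig(seed=3))
for est in analysis.estimates:
    print(f"D{est.q:g} = {est.value:.4f} +/- {est.std_error:.4f}  "
          f"(R^2 = {est.r_squared:.4f})")
```

prints

```
unfiltered: accuracy 0.9963, fat fraction 0.1798
hp25: accuracy 1.0000, fat fraction 0.1835
D0 = 1.7732 +/- 0.0384  (R^2 = 0.9953)
D1 = 1.7334 +/- 0.0299  (R^2 = 0.9970)
D2 = 1.7065 +/- 0.0226  (R^2 = 0.9983)
```

Under strong shading the unfiltered threshold mislabels the fat lying
in the darkened part of the field (accuracy 99.63 %), while the 25-px
high-pass path recovers the ground truth exactly. The dimensions obey
D₀ ≥ D₁ ≥ D₂, and every regression standard error is far below the
0.1 suitability bound for dimension estimates.

## Analysis drivers and CLI

The `analysis/` scripts run the full study on a synthetic four-class
fixture (fat fractions 10/15/20/30 %) and write tables under
`results/`:

```
python analysis/01_generate_fixture.py   # slices + ground truth + manifest
python analysis/02_segment.py            # 3 methods, exact accuracy scores
python analysis/03_dimensions.py         # sandbox D0/D1/D2 per mask
python analysis/04_summarize.py          # mean±SE tables, scatter, box stats, IQRs
```

The same stages are available as a CLI for arbitrary images:
`hamfrac generate|pipeline|mfa|run|summarize` (see `--help`); `hamfrac
run --config cfg.yaml` executes an entire configured batch
deterministically and writes a provenance manifest.

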
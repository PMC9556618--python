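# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `rnfl-quant`. It is the design rationale; every
empirical number it refers to is computed by the test suite or by
`scripts/acceptance.py`, not asserted here.

## Synthetic circle-scan phantoms

**What is emulated.** A circumpapillary OCT B-scan is modelled as three
piecewise-constant layers on an H×W grid (default 256×256, one column per
A-scan): vitreous (intensity 0.08), the RNFL band (0.85) and deeper retina
(0.45), warped by a slowly undulating inner limiting membrane (ILM; mean
depth 60 px, sinusoidal amplitude 6 px with a seeded phase). The band's
per-column thickness follows the classic TSNIT double-hump curve

    t(θ) = s · [ b + A·G(θ; 67.5°, σ) + A·G(θ; 292.5°, σ) ] + j(θ)

with Gaussian humps G (σ = 26° by default) at the superior- and
inferior-temporal bundle peaks (the centres of the TS and TI sectors),
a per-phantom global scale `s`, and smooth angular jitter `j`. Speckle is
multiplicative gamma noise with unit mean (shape 4 by default; lower is
noisier), the standard first-order model for coherent-imaging noise.
Optional artifacts: a detached epiretinal membrane (a thin bright line a
few pixels above the ILM over a random arc) and a partial posterior
vitreous detachment (a faint oblique line in the vitreous). Both perturb
the image only, never the ground truth.

**Calibration.** The three group presets solve the baseline `b` so that the
noise-free circle average equals the published cohort means of manually
segmented scans: control 100.3 µm, NAION 69.7 µm, ON 76.1 µm. Hump
amplitudes (60 / 35 / 40 µm) keep the qualitative sector ordering
(inferior-temporal thickest, temporal/nasal thinnest) without attempting
per-sector fidelity, which the phantom does not target.

**Variability.** The scale `s` is drawn from a normal with SD 0.10,
truncated symmetrically at ±3 SD so its mean is exactly 1 and the
Monte-Carlo mean of the circle average converges to the preset target. The
jitter is a sum of Fourier modes k = 1…4 with Gaussian coefficients
(SD 2 µm); on the discrete circle these modes have exactly zero mean, so
jitter never biases the circle average. A 10 % coefficient of variation is
a deliberate understatement of clinical between-eye spread (NAION cohorts
show CVs near 30 %): the phantom family is meant to exercise the
measurement chain, not to emulate population heterogeneity.

**What the phantoms do not emulate** — and hence what passing tests do not
show about real data: vessel shadows, true OCT speckle statistics
(correlated, depth-dependent), curved/tilted retinas, signal roll-off,
segmentation-relevant pathology other than global thinning. Results on
phantoms demonstrate the correctness of the pipeline's plumbing and the
learnability of the synthetic task, not clinical performance.

**Seeding.** One master seed; child seeds for phantom *i* are derived with
a splitmix64 finalizer at indices 2i (profile) and 2i+1 (renderer), then
reduced below 2³¹. Identical (spec, seed) reproduces bit-identical outputs
on any platform; dataset prefixes are stable under growth of n.

## Preprocessing

Speckle denoising is grayscale morphological opening followed by closing
with a 3×3 square structuring element — opening first because bright
speckle is the dominant OCT artifact. The composite never widens the
intensity range and is idempotent in practice.

Network input preparation: images at or below 256×256 are zero-padded
symmetrically (odd leftover to the bottom/right); larger images (e.g. a
496×768 Spectralis-like grid) are first downscaled isotropically with
bilinear interpolation so the longer side equals 256 — the shorter side
rounds **up** (integer ceiling, computed in exact integer arithmetic), so
no content is cropped — then padded. The `ScaleInfo` record (scale factor,
pad offsets, original dims) inverts the transform exactly; predicted masks
return to the original grid by crop + nearest-neighbour upsampling, which
preserves binarity. The default phantom grid is 256×256 native so the core
tests isolate segmentation correctness from resampling; the Spectralis-like
mode exercises the resize path separately.

## U-Net

Standard encoder–decoder: per level two 3×3 same-padding convolutions with
ReLU, 2×2 max-pool between levels, filter ladder (16, 32, 64, 128, 256)
— a 256×256 input reaches a 16×16 bottleneck — then a symmetric decoder
with 2×2 up-convolutions, skip concatenations, and a 1×1 convolution to a
single logit; a logistic sigmoid yields the probability map and 0.5 is the
default binarisation threshold (exposed as a flag).

The implementation is pure NumPy: activations are channels-last and each
3×3 convolution is nine shifted matrix multiplications (substantially
faster on one CPU core than an explicit im2col buffer at these channel
counts); backpropagation is hand-derived per layer and verified against
central finite differences in the test suite. Weights are He-normal
initialised from a seeded generator.

Training: binary cross-entropy on the logits (numerically stable softplus
form), Adam (lr 1e-3, β = 0.9/0.999), batch size 8, 50 epochs by default —
optimiser, rate and schedule are not dictated by the problem and are all
exposed in `TrainConfig`. Scans are split 80/20 into training/validation at
the scan level so no image contributes pixels to both sides. The weights
returned are those of the epoch with the lowest validation loss
(`restore_best`, default on): full-batch Adam on small datasets
occasionally produces a late loss spike, and best-epoch restoration makes
the delivered model insensitive to where such a spike falls. Because every
source of randomness is a seeded NumPy generator, training is
deterministic given (data, config) unconditionally; there is no separate
non-deterministic fast path.

Scaled-down training analogue: the property-level check trains a reduced
ladder (8, 16, 32) on 40 phantoms for 16 epochs (batch 4) and evaluates on
10 held-out phantoms. These sizes keep a full run in the low minutes on a
single core while leaving headroom above the Dice ≥ 0.80 / MAE ≤ 5 µm
property being checked; it is an analogue of clinical performance figures,
not a reproduction of them.

## Post-processing and thickness

Mask cleaning fills interior holes (flood-fill from the border complement)
and removes 8-connected components with area strictly below 25 px (at
256-A-scan width; exposed as a flag — the threshold is a speckle-size
prior, not a fitted value).

Thickness per A-scan: the **column method** (default reporting estimator)
counts mask pixels per column × axial spacing (3.87 µm/px, the Spectralis
nominal; configurable since devices differ). The **EDT method** takes twice
the per-column maximum of the 2-D Euclidean distance transform. For
horizontal bands the two agree within one axial pixel (exact for even
heights, 1 px for odd — the EDT rounds the half-thickness up). On sloped
boundaries the 2-D transform is reduced diagonally by thinner neighbouring
columns, so per-column deviations can exceed a pixel locally; the tests
therefore assert exact agreement on bands and close average agreement on
phantoms. The EDT is kept as a cross-check, not the reporting path.

Sector analysis: A-scan *i* sits at i·360/n on the unrolled TSNIT axis with
A-scan 0 on the temporal meridian. Sector spans follow the Spectralis
convention — temporal 315°–45°, TS 45°–90°, NS 90°–135°, nasal 135°–225°,
NI 225°–270°, TI 270°–315° — half-open `[start, end)` and configurable,
since the sector names are standard but published span definitions vary.
The reported average is the plain mean over all A-scans; when n is a
multiple of 8 the sectors partition the columns exactly and the average
equals the width-weighted sector mean to machine precision (asserted).
Left eyes (OS) are handled by reflecting the angular mapping about the
vertical (superior–inferior) axis, a′ = (180° − a) mod 360°, which swaps
nasal↔temporal labels while keeping superior sectors superior; because a
reflection reverses orientation, span membership flips to `(start, end]`
for OS so the sectors remain an exact partition.

Degenerate inputs: an empty column reports 0 µm; an all-empty mask reports
a zero profile under both estimators; a sector with no A-scans (possible
only for n < 8) reports NaN rather than silently extrapolating.

## Evaluation metrics

Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), computed per scan with the reference mask as truth and averaged
across scans (pooled-pixel aggregation is a flag); empty-vs-empty Dice is
1.0 by convention and the convention's use is recorded in the result.
Thickness error is the mean absolute error against the phantom's continuous
ground-truth profile; correlation is the sample Pearson coefficient
(undefined, and refused, for zero-variance input).

## Pipeline modes and determinism

`oracle` mode feeds ground-truth masks through post-processing — the
manual-segmentation reference arm — and must recover sector means to within
quantisation (≤ ½ axial pixel per column) with Dice exactly 1. `corrupt`
mode truncates the band over a random 25 % arc, a stylised segmentation
failure standing in for error-prone machine segmentation; its
average-thickness MAE exceeds the oracle's by construction, mirroring the
clinically observed ordering. `train`/`untrained` modes segment with the
network. All CSV/JSON outputs carry a hash of the scientific configuration
(output paths and log level excluded), and re-running a configuration
reproduces the CSVs byte for byte.

## Known limitations

- The phantom's simplicity means segmentation on it is far easier than on
  clinical scans; Dice values here do not transfer.
- No cross-device generalisation, vessel handling, or 3-D context.
- The NumPy network trains CPU-only at small scale; it is not a framework
  replacement, and large-scale training is out of scope.
- Group-level statistics (ANOVA/Kruskal–Wallis etc.) are deliberately out
  of scope; the reports expose per-scan values for external analysis.
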
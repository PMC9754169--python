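# Methods

## Problem

Abdominal CT is routinely acquired anisotropically: ~1 mm in-plane
resolution but 2.5 mm or more between slices (slice increment), because
denser sampling along the longitudinal (z) axis costs radiation dose.
`ctdense` reconstructs the missing through-plane information: given a
sparsely sliced volume, it synthesizes the 2m − 1 slices between each
pair of adjacent slices, producing a densely sliced volume without any
change to the acquisition.

## Reconstruction model

Let S_1 … S_n be the dense slice sequence. The sparse subset keeps every
2m-th slice starting at S_1; each retained pair (S_t−m, S_t+m) bounds a
gap of 2m − 1 missing slices. A gap is reconstructed by a **parallel
architecture**: 2m − 1 U-nets with independent parameters, all fed the
identical two bounding slices (stacked as two input channels), each
dedicated to one target position. Independence prevents the
reconstructed positions from influencing one another; branch k's output
is invariant to the existence or training of any other branch, which the
tests assert exactly. A single-network variant emitting all 2m − 1
slices in one forward pass is provided as the comparison architecture.

Each branch is an encoder–decoder network with skip connections: by
default eight encoder and seven decoder modules (convolution + batch
normalization + ReLU; dropout in the last decoder block), channel widths
doubling from `base_channels` and capped at 512, with a final 1×1
projection. The effective depth auto-reduces for small images so every
resolution level keeps a spatial extent of at least 2; inputs whose
sides are not divisible by the pooling factor are edge-padded internally
and cropped on output, so output shape always equals input shape.

**Residual prediction.** Branch k does not regress the target slice
directly; it predicts the correction to the linear blend
(1 − k/2m)·left + (k/2m)·right, with a zero-initialized projection head.
An untrained branch therefore reproduces linear interpolation exactly,
and training can only move away from that anchor where the data support
it. Predicting the interpolation residual is the standard conditioning
device in learned super-resolution; it leaves the encoder–decoder
architecture untouched and makes short CPU-scale training well-posed.
Disable with `UnetSpec(residual=False)`.

The convolutional backend (`_nn.py`) is a compact numpy implementation —
im2col convolutions over BLAS, batch normalization, 2×2 average pooling,
nearest-neighbor upsampling, inverted dropout, Adam — with handwritten
backward passes verified against numerical differentiation during
development. Everything is float32 and fully deterministic given a seed.

## Intensity domain

Voxels are clipped to a fixed [−1000, 1000] HU window and mapped
affinely onto [0, 1]. The window is fixed rather than per-volume so
training and test volumes share one intensity domain; values outside it
(dense bone, metal) are clamped and not modeled. All learning, range
estimation and reconstruction happen on the normalized scale; MAE is
converted back to HU (×2000) for reporting.

## Organ range-clip enhancement

A single organ occupies a narrow band [R_ll, R_lh] of the normalized
scale. The range-clip transform

f(x) = 0 for x < R_ll; 1 for x > R_lh; B(x − C) otherwise, with
C = R_ll and B = 1/(R_lh − R_ll),

is the unique affine map stretching the organ band onto [0, 1]. A second
parallel model trained on f-transformed volumes concentrates its
capacity on the organ's intensities; at inference f is applied to the
inputs and f⁻¹ to the outputs, and the organ's voxels in the base
reconstruction are replaced by that organ model's output
(**organ-oriented reconstruction**). f is lossy outside the band — f⁻¹∘f
collapses sub-band values to R_ll — which is exactly why the base model
keeps authority outside the organ masks; replacement is per-voxel, masks
may not overlap, and voxels outside all masks are bit-equal to the base
prediction.

The band is estimated from labeled training volumes with percentile
trimming (default 0.5–99.5%), which stands in for manual removal of
outlier intensities from foreign objects (staples, drainage tubes). Gas
in the stomach sits near the air end of the scale; voxels below a
threshold (default 0.25 ≙ −500 HU) are excluded from stomach band
estimation and from replacement. Reference (C, B) constants published
for a 130-patient abdominal cohort are bundled
(`REFERENCE_ABDOMINAL_PARAMS`) and can be loaded instead of fitting.
(Under the fixed window the reference liver band maps to −200…+240 HU,
lower than typical liver attenuation; the original normalization may
have differed from ours, so the constants are shipped verbatim while
fitted bands remain the primary path.)

Test-time organ masks are an explicit input: evaluation uses dense
ground-truth labels; pure inference interpolates masks from the two
bounding-slice labels (membership ≥ 0.5). The package deliberately does
not ship a segmenter.

## Evaluation protocol

MAE in HU, pooled over voxels per target position (position k of the
2m − 1 in a gap, pooled across gaps and volumes; per-organ variants
restrict to masks). SSIM per slice after independent min-max
normalization of each slice (z-score selectable), Gaussian window
(σ = 1.5, window 7 by default), standard stabilization constants;
a constant slice cannot be normalized and is compared unnormalized
(logged). Improvements are 100·(ref − new)/ref for errors and
100·(new − ref)/ref for similarities. Significance uses the two-sided
paired Wilcoxon signed-rank test on per-gap per-position mean absolute
errors (paired t-test selectable); identical samples are flagged
degenerate rather than assigned significance. The half-gap parameter m
is chosen by the μ rule: the largest m whose maximum pixel-wise MAE
stays within a threshold μ; if even the smallest m exceeds μ it is
returned with a warning.

## Synthetic phantoms

No clinical volumes ship with the package; the phantom generator
emulates the statistical structure the method relies on:

- smooth wide-range background (sum of low-frequency 3-D cosine modes);
- four ellipsoidal "organs" whose intensities occupy narrow sub-bands —
  defaults are the reference abdominal bands (liver 0.400–0.620,
  left kidney 0.418–0.628, right kidney 0.440–0.600, stomach
  0.320–0.570);
- organ centers drifting sinusoidally in-plane along z (amplitude ~5% of
  the field of view ≈ 3 px at 64², ~1 cycle per volume) and radii
  pulsing ±20% — nonlinear through-plane change, so linear interpolation
  ghosts at organ boundaries;
- an air pocket inside the stomach at intensity ≈ 0.02, labeled as
  stomach, so the air filter has real work;
- i.i.d. Gaussian noise (σ = 0.01 ≙ 20 HU) and per-volume jitter of
  positions, phases, amplitudes and band shifts (±0.005) emulating
  inter-patient variation.

An `affine` mode generates static organs with intensities affine in
slice index, on which linear interpolation is provably exact — the
analytic oracle anchoring the baseline tests.

What the phantoms do **not** have: anatomy, CT physics (beam hardening,
partial volume, structured noise), bone/air anatomy outside the stomach
pocket, or realistic organ texture. Passing the phantom study shows the
pipeline's machinery is correct and that the learned reconstructor
exploits nonlinear through-plane structure better than linear
interpolation under these conditions; it does not certify clinical
performance.

## Desk-scale study conditions

The end-to-end study (`pipeline.run_study`, also behind
`ctdense study` and `scripts/acceptance.py`) uses 30 phantom volumes of
25×64×64 voxels, an 80/20 volume-level split, targets_per_gap = 3
(m = 2, six gaps per volume), and a 4-level U-net with 8 base channels —
sizes chosen so the whole study trains on one CPU core in minutes.
Training: MAE loss (the evaluation criterion, optimized directly since
the reference training loss is unpublished; squared error selectable),
Adam at 5·10⁻³ with cosine decay to a tenth, batch 8, 15 epochs,
dropout 0.2 in the last decoder block, 10% validation split.
Augmentation doubles each gap by traversing it in the opposite
longitudinal direction (inputs swapped, positions reversed — exact by
symmetry) and applies random in-plane mirror flips per batch. The liver
model is trained on range-clip-transformed data with the band estimated
from the training split. All randomness derives from one master seed
(dataset jitter, splits, initialization, shuffling, dropout); reruns are
bit-identical.

## Numerical choices and edge cases

- Interpolation fractions are uniform k/(2m): the natural choice for
  equally spaced slices.
- Trailing dense slices that do not complete a final gap are excluded
  from both groups and reported, not padded or mirrored.
- Originals are always copied bit-for-bit into the merged volume, never
  re-synthesized.
- Grouping indices are 1-based in user-facing structures (S_t
  convention), 0-based internally.
- Degenerate inputs raise: zero-width organ band, empty evaluation mask,
  overlapping organ masks, groupings that exceed the volume extent.
- Predictions are clamped to [0, 1] at inference.
- The longitudinal axis defaults to the axis with the largest voxel
  spacing; DICOM series take the inter-slice distance (not
  SliceThickness) as the longitudinal spacing and reject series with
  inconsistent steps.

## Known limitations

- The residual anchor biases branches toward linear interpolation; for
  severely nonlinear motion a free-standing network might eventually do
  better given much longer training.
- Pooled-voxel MAE (default) weights volumes by voxel count; a
  per-patient average is available behind the report's per-sample
  errors.
- The numpy backend is single-core and desk-scale; the full 400×320
  clinical geometry builds and runs forward passes, but training at that
  scale wants a GPU framework.
- Non-integer m is represented exactly by its integer target count
  2m − 1; no fractional slice positions are resampled.
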
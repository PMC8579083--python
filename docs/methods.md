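# Methods

`metrano` automates the serial-read workflow for brain metastases (BM) on
contrast-enhanced 3D T1-weighted MRI: detect enhancing nodules, segment
each one finely, measure it, match lesions across a baseline/follow-up
pair, and classify the change under a modified RANO-BM rule set on both a
diameter and a volume basis. This note records the models, the defaults
and why, the numerical conventions, and what the synthetic phantoms do and
do not establish.

## Geometry conventions

Axis order is `(x, y, z)` with `z` axial; indices are 0-based and
voxel-centered (`world = origin + index * spacing`); boxes are half-open
`[lo, hi)`. NIfTI-1 is the only on-disk image format; images are
reoriented to the closest-to-RAS convention on read. All diameters are
measured in the axial plane, volumes in mm³ (voxel count x voxel volume).

## Pipeline stages

**Normalization.** Scanner intensities are arbitrary, so each scan is
mapped by `v -> clip(v / (2 * g), 0, 1)` where `g` is a gray-matter
reference intensity; `g` maps to 0.5 and the background (outside the brain
mask) is forced to exactly 0. By default `g` is the median intensity of
the brain mask — an automated surrogate for picking a gray-matter point by
hand — and can be overridden when the reference is known. The mapping is
monotone, idempotent at `g = 0.5`, and invertible below the clip.

**Brain masking and cropping.** The default masker is an Otsu threshold
followed by largest 26-connected component, morphological closing and
axial slice-wise hole filling; any trainable segmenter with a
`predict(data)` method can be substituted. Detection is restricted to the
tight brain box plus a 2-voxel margin, which both removes false positives
outside the head and shrinks the detector's input.

**Cube resampling.** The cropped volume is resampled into an isotropic
cube (192³ at clinical scale; 64³ in the tiny CPU profile) with *one*
global scale factor `size / max(physical extent)` on all axes, so aspect
ratio is preserved and the remainder is zero padding, content centered.
The resample record stores the exact closed-form index mapping, so labels
and boxes round-trip to the native grid with no drift.

**Coarse detection.** A 3D encoder-decoder segmenter is trained under the
Dice loss `1 − 2Σpt/(Σp + Σt + ε)` (ε = 1e-7), which is robust to the
extreme foreground/background imbalance of small metastases in a whole
head. Its thresholded probability map (cutoff 0.5) is split into
26-connected components; components under 2 voxels are discarded; each
surviving component's bounding box (plus a 1-voxel margin) seeds
refinement. 26-connectivity and the 0.5 / 2-voxel defaults are fixed,
configurable conventions so counts are reproducible.

**Fine segmentation.** Each detected box is expanded by 25% per axis
(minimum 8 voxels per side), and every axial slice of it is upsampled to a
square patch (512² clinical, 128² tiny) preserving in-plane aspect ratio
with zero padding. A 2D encoder-decoder segments every patch; thresholded
results are mapped back through the recorded patch geometry
(nearest-neighbor) and unioned in 3D. An all-background prediction vetoes
the candidate. Overlapping per-lesion masks are OR-ed and relabeled by
connected components. Passing all slices of the box through the 2D model
(rather than a single representative slice) is this package's choice. A
pretrained encoder is not used; weights start from a seeded He
initialization.

**The network.** Both segmenters share one architecture, implemented
directly on numpy: conv3(1→C) → ReLU → 2x average pool → conv3(C→2C) →
ReLU → 2x nearest upsample → skip concatenation → conv1(3C→C) → ReLU →
conv1(C→1) → sigmoid, with C = 8 by default. Convolutions run as sums of
shifted tensor contractions (one small GEMM per kernel offset), gradients
are hand-derived and verified against finite differences, and
optimization is Adam (batch size 1). The reference schedule is 300 epochs
at learning rate 1e-3 dropping to 1e-4 at epoch 100 and 1e-5 at epoch 250;
the tiny profile keeps the same decay shape compressed into a short run
(10 epochs at 3e-3 for the detector, 2 for the refiner). Two numerical
choices matter for convergence under the Dice loss: the output bias is
initialized to −4 so the initial foreground probability (~0.018) avoids
the loss's degenerate flat region, and the 3D detector draws several
random 32³ sub-cubes per volume per epoch (70% centered on lesion voxels)
— the network is fully convolutional, so small-crop training transfers to
whole-cube inference while multiplying the number of optimization steps.
Augmentation is flips, 90° rotations, small translations and mild
intensity scaling in 3D, and a deterministic 16-fold
flip/rotation/translation expansion for 2D patches.

**Quantification.** Volume is exact voxel counting. The longest axial
diameter is, per axial slice, the maximum pairwise distance between
in-plane voxel centers (convex-hull shortcut above 400 voxels, verified
against the all-pairs scan) plus the mean in-plane voxel size as an
outer-edge correction, maximized over slices. The correction makes a
single voxel measure one voxel rather than zero and keeps the 5 mm
measurability cutoff meaningful at 1 mm resolution.

**Registration and matching.** Serial scans are aligned with a similarity
transform — Euler XYZ rotation, translation, and one isotropic scale,
about the brain-mask centroid of the fixed scan (a `rigid` flag freezes
scale at 1; both modes exist because repositioning is rigid but minor
calibration drift is not). Optimization is multi-resolution (shrink 4/2/1,
smoothing 2/1/0 mm) mean-squared-difference descent via SimpleITK, with a
tight gradient-magnitude tolerance (1e-10) because smooth scans provide
weak rotation gradients near the optimum; mutual information is available
for cross-protocol pairs. Lesions are then matched one-to-one: baseline
centroids map through the transform, candidate pairs must lie within
`max(5 mm, r_b + r_f)` (equivalent-sphere radii), and assignment minimizes
total distance (Hungarian algorithm).

**Response rules.** Up to five target lesions with longest diameter
≥ 5 mm are selected at baseline (diameter descending; ties by volume then
id) and tracked forward — no re-selection at follow-up. With `S` the sum
of target diameters: any new lesion ⇒ PD; `S_f = 0` ⇒ CR; change ≤ −30% ⇒
PR; ≥ +20% ⇒ PD; else SD; boundaries inclusive. The volumetric variant
uses total target volume with the cubed thresholds 0.7³ = 0.343 and
1.2³ = 1.728, so an isotropic diameter change lands in the same category
on both bases; both threshold sets are configurable. Sub-measurable
lesions influence the result only through the new-lesion rule.

**Metrics.** A truth lesion counts as detected when any predicted voxel
overlaps it (a centroid-inside-truth criterion is available); each
predicted component overlapping no truth lesion is one false positive.
Dice is reported per matched lesion as mean ± SD. Agreement between two
ordered CR/PR/SD/PD ratings is Cohen's weighted kappa with linear weights
`w_ij = 1 − |i−j|/3` by default (quadratic available), with the
conventional verbal bands (0.41–0.60 moderate, 0.61–0.80 substantial).
Binomial proportions carry exact Clopper-Pearson 95% intervals by default;
the Wilson score interval is available by flag because published CIs in
this area are not always computed one way.

## The phantom generator

Real serial MRI with expert lesion annotations cannot ship with a
package, so all tests run on a parametric phantom: a distinctly triaxial
brain ellipsoid (radii fractions 0.34/0.40/0.28 of the grid — all three
axes differ, as in a real head, so every rotation component is observable
to registration) with smooth seeded sinusoidal shading (±8%) around a
gray-matter level of 100, quasi-spherical hyperintense lesions (contrast
1.5–3.0x gray matter, clinical-like diameters, defaults 3–14 mm at full
scale and 3–10 mm in the 64³ tiny profile with 2–3 lesions per scan),
additive Gaussian noise (σ = 3) inside the brain, and an exactly zero
background. Follow-up scans are *rendered analytically*: every implicit
anatomy function is evaluated at the inverse-transformed grid
coordinates, so the recorded transform, per-lesion masks, centers and
diameters are exact rather than interpolated, and an identity transform
with the same noise seed reproduces the baseline bit-for-bit.
Longitudinal cohorts cycle through five scenarios (CR: all lesions
removed; PR: radii x0.55–0.62; SD: x0.97–1.05; PD: x1.30–1.40; PD by a
new 3 mm lesion) under moderate transforms (±5°, ±3 mm, scale
0.985–1.015); response cohorts restrict lesions to 6–12 mm so the truth
target set is stable under the outer-edge diameter convention.

What the phantom does *not* emulate: gyral/sulcal anatomy, CSF and
vasculature, bias fields, partial-volume effects beyond voxelization,
rim-enhancing or confluent lesions, and low-contrast metastases. Passing
tests therefore establish that the pipeline's geometry, bookkeeping,
training machinery, registration and rules are correct and
well-calibrated on well-separated enhancing nodules — not that the tiny
CPU models would reach clinical-grade sensitivity on patient data.

## Problem sizes

The bundled tests and the acceptance script use the tiny profile: 64³
phantoms, 20 training volumes, 20-pair evaluation cohorts, 10/2 training
epochs for detector/refiner. These sizes are the package's chosen
desk-scale study conditions; the `clinical` profile (192³ cube, 512²
patches, 300-epoch schedule) is fully supported through configuration.

## Known limitations

* The refiner segments slices independently; a 3D refiner might do better
  on lesions spanning many slices.
* Matching is centroid-based; confluent or splitting lesions are matched
  to at most one counterpart.
* Kappa confidence intervals are not computed.
* The volumetric thresholds are the cubes of the diameter thresholds by
  geometric correspondence; other published volumetric cutoffs can be set
  via the configurable thresholds.
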
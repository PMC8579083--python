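# metrano

Automated detection, segmentation, longitudinal matching and
treatment-response assessment of **brain metastases (BM)** on
contrast-enhanced 3D T1-weighted MRI.

Assessing treatment response in patients with BM means finding every
enhancing nodule on a thin-slice 3D scan (often hundreds of slices),
measuring each one, re-identifying the same nodules on the follow-up
scan, and applying the RANO-BM rules — a labor-intensive serial read that
this package automates end to end. It is aimed at researchers in
neuro-oncology imaging who want a testable, fully scripted reference
pipeline, complete with a synthetic phantom generator that provides exact
ground truth for every stage.

## The pipeline

For each scan: intensity normalization anchored on a gray-matter
reference (`v → clip(v/2g, 0, 1)`, background exactly 0) → brain mask and
crop → aspect-preserving resample into an isotropic cube (192³; 64³ in
the CPU `tiny` profile) → coarse 3D encoder-decoder detection under the
Dice loss → per-candidate fine 2D segmentation on upsampled axial patches
(512²/128²) → stitching, 26-connected labeling and volumetry.

For a baseline/follow-up pair: similarity registration (Euler rotations
**R**, translation **t**, isotropic scale *s*; `y = c + sR(x−c) + t`) →
one-to-one lesion matching (Hungarian assignment on mapped centroids) →
modified RANO-BM classification. With *S* the sum of longest axial
diameters of up to five target lesions (measurable at ≥ 5 mm on 1 mm
slices):

| rule | category |
|---|---|
| any new lesion, regardless of size | PD |
| S_f = 0 | CR |
| ΔS/S_b ≤ −30% | PR |
| ΔS/S_b ≥ +20% | PD |
| otherwise | SD |

The volumetric variant applies the cubed thresholds (0.7³ = 0.343,
1.2³ = 1.728) to total target volume. Agreement between two ordered
CR/PR/SD/PD ratings is Cohen's weighted kappa with linear weights
w_ij = 1 − |i−j|/3; binomial sensitivities carry exact Clopper-Pearson
95% intervals.

Both segmenters are compact U-Net-style encoder-decoders implemented
directly on numpy (hand-derived gradients, Adam, Dice loss) — small
enough to train on one CPU at the tiny profile, with the full-scale
schedule (300 epochs, LR 1e-3 → 1e-4 @ 100 → 1e-5 @ 250) available
through configuration. See `docs/methods.md` for the full model account.

## Worked example

Simulate a two-timepoint phantom patient and assess response with the
oracle path (ground truth replayed as model probabilities — no training
needed):

```bash
$ metrano simulate --n-pairs 2 --seed 3 --out cohort
wrote cohort/manifest.json

$ metrano assess cohort/sub001_baseline.nii.gz cohort/sub001_followup.nii.gz \
    --oracle-baseline-labels cohort/sub001_baseline_labels.nii.gz \
    --oracle-followup-labels cohort/sub001_followup_labels.nii.gz \
    --out assessment.json
1D: PR  volumetric: PR; wrote assessment.json
```

`assessment.json` records the recovered inter-scan transform and the
numbers behind the call: the baseline diameter sum over the target
lesions was 24.6 mm, the follow-up sum 15.2 mm (−38.5%, beyond the −30%
cutoff → partial response), and the target volume fell from 805 mm³ to
184 mm³ (−77.1%, beyond the volumetric cutoff → PR on both bases).

Computing agreement between two raters' response tables:

```bash
$ metrano kappa table.csv
kappa (linear): 0.5238 [moderate]
```

Training your own tiny-profile models and scoring them on fresh phantoms:

```bash
metrano train-detector --n-volumes 20 --seed 0 --out detector.npz
metrano train-refiner  --n-volumes 20 --seed 0 --out refiner.npz
metrano evaluate --n-pairs 5 --seed 9 --detector detector.npz --refiner refiner.npz --out metrics.json
```

The library mirrors the CLI: `MetastasisDetector3D` and `LesionRefiner2D`
are scikit-learn-style estimators (`fit`/`predict`, `loss_history_`), and
`metrano.pipeline` exposes `segment_scan`, `assess_pair`, `make_cohort`
and `evaluate_cohort`.

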
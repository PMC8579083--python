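"""End-to-end orchestration: scan -> lesions -> longitudinal assessment.

The full chain per scan is: intensity normalization -> brain mask -> crop
-> isotropic-cube resample -> coarse 3D detection -> per-lesion 2D fine
segmentation -> stitching and labeling -> volumetry. For a baseline/
follow-up pair the two scans are registered with a similarity transform,
lesions are matched one-to-one, and a modified RANO-BM response category
is produced on both the diameter and the volume basis.

Every stage accepts an *oracle* mode in which ground-truth probabilities
stand in for model outputs; this exercises all geometry and rules without
any training and is the reference path for pipeline integrity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phantom as ph
from .detect import MetastasisDetector3D, detect_lesions, extract_bounding_boxes
from .evaluate import (
    ConfusionTable4,
    DetectionEval,
    match_detections_to_truth,
    per_lesion_dice,
    weighted_kappa,
)
from .longitudinal import (
    LesionMatchSet,
    match_lesions,
    register_similarity,
    registration_success_rate,
)
from .preprocess import (
    NormalizedVolume,
    crop_to_brain,
    extract_brain_mask,
    normalize_intensity,
    resample_isotropic_cube,
)
from .quantify import LesionRecord, lesion_records
from .rano import ResponseAssessment, assess_study_pair
from .refine import LesionRefiner2D, assemble_lesion_map, crop_and_upsample, refine_lesion
from .transform import SimilarityTransform
from .volio import BoundingBox, LabelMap, Volume3D

__all__ = [
    "PipelineProfile",
    "OracleProbabilityModel",
    "IdentityProbabilityModel",
    "SegmentationResult",
    "segment_scan",
    "assess_pair",
    "truth_records",
    "truth_match_set",
    "truth_assessment",
    "make_cohort",
    "evaluate_cohort",
    "train_models_from_phantoms",
]


@dataclass
class PipelineProfile:
    """Per-stage sizes and thresholds.

    ``clinical`` mirrors the full-scale deployment (192³ detection cube,
    512² refinement patches); ``tiny`` is the desk-scale profile used for
    CPU tests (64³ / 128²).
    """

    cube_size: int = 192
    patch_size: int = 512
    crop_margin_voxels: int = 2
    box_margin_cube: int = 1
    refine_margin_frac: float = 0.25
    detect_threshold: float = 0.5
    min_voxels: int = 2
    min_diameter_mm: float = 5.0
    max_targets: int = 5

    @classmethod
    def clinical(cls) -> "PipelineProfile":
        return cls()

    @classmethod
    def tiny(cls) -> "PipelineProfile":
        return cls(cube_size=64, patch_size=128)


class OracleProbabilityModel:
    """Replays a fixed probability map regardless of input intensities."""

    def __init__(self, prob: np.ndarray):
        self.prob = np.asarray(prob, dtype=np.float32)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if np.asarray(x).shape != self.prob.shape:
            raise ValueError(f"oracle map shape {self.prob.shape} != input {np.asarray(x).shape}")
        return self.prob


class IdentityProbabilityModel:
    """Returns its input clipped to [0, 1]; used with truth-mask patches."""

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=np.float32), 0.0, 1.0)


@dataclass
class SegmentationResult:
    labels: LabelMap
    records: list[LesionRecord]
    normalized: NormalizedVolume
    crop_box: BoundingBox
    detect_boxes_native: list[BoundingBox] = field(default_factory=list)


def _shift_box(box: BoundingBox, lo: tuple[int, int, int], grid_shape) -> BoundingBox:
    new_lo = tuple(min(max(0, a + d), n - 1) for a, d, n in zip(box.lo, lo, grid_shape))
    new_hi = tuple(min(max(b + d, al + 1), n) for b, d, al, n in zip(box.hi, lo, new_lo, grid_shape))
    return BoundingBox(new_lo, new_hi)


def segment_scan(
    vol: Volume3D,
    detector: MetastasisDetector3D | None = None,
    refiner: LesionRefiner2D | None = None,
    profile: PipelineProfile | None = None,
    gm_reference: float | str = "auto",
    oracle_labels: LabelMap | None = None,
) -> SegmentationResult:
    """Run the full single-scan chain.

    Either trained ``detector``/``refiner`` estimators or ``oracle_labels``
    (ground truth replayed as model probabilities) must be provided.
    """
    profile = profile or PipelineProfile()
    oracle = oracle_labels is not None
    if not oracle and (detector is None or refiner is None):
        raise ValueError("need a fitted detector and refiner, or oracle labels")

    mask = extract_brain_mask(vol)
    norm = normalize_intensity(vol, gm_reference, background_mask=~mask.mask())
    crop, crop_box = crop_to_brain(norm.volume, mask, profile.crop_margin_voxels)
    cube, record = resample_isotropic_cube(crop, profile.cube_size)

    if oracle:
        truth_crop = oracle_labels.labels[crop_box.slices()]
        det_model = OracleProbabilityModel((record.resample_labels(truth_crop) > 0).astype(np.float32))
    else:
        det_model = detector
    det_labels = detect_lesions(
        cube.data, det_model, profile.detect_threshold, profile.min_voxels, cube.spacing
    )

    if oracle:
        patch_source = (oracle_labels.labels > 0).astype(np.float32)
        ref_model = IdentityProbabilityModel()
    else:
        patch_source = norm.volume.data
        ref_model = refiner

    masks = []
    boxes_native = []
    for cbox in extract_bounding_boxes(det_labels, margin=profile.box_margin_cube):
        nbox = _shift_box(record.box_to_native(cbox), crop_box.lo, vol.shape)
        boxes_native.append(nbox)
        patches = crop_and_upsample(patch_source, nbox, profile.patch_size, profile.refine_margin_frac)
        masks.append(refine_lesion(patches, ref_model, vol.shape))
    labels = assemble_lesion_map(masks, vol.shape, vol.spacing, vol.origin)
    return SegmentationResult(labels, lesion_records(labels), norm, crop_box, boxes_native)


@dataclass
class PairAssessment:
    transform: SimilarityTransform
    matches: LesionMatchSet
    one_d: ResponseAssessment
    volumetric: ResponseAssessment
    baseline: SegmentationResult
    followup: SegmentationResult

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "matches": self.matches.to_dataframe().to_dict("records"),
            "one_dimensional": self.one_d.to_dict(),
            "volumetric": self.volumetric.to_dict(),
        }


def assess_pair(
    baseline: Volume3D,
    followup: Volume3D,
    detector: MetastasisDetector3D | None = None,
    refiner: LesionRefiner2D | None = None,
    profile: PipelineProfile | None = None,
    oracle_labels: tuple[LabelMap, LabelMap] | None = None,
    transform: SimilarityTransform | None = None,
) -> PairAssessment:
    """Segment both scans, register, match lesions, and assess response.

    ``transform`` may supply a known inter-scan transform, bypassing
    registration (used when an upstream step already aligned the pair).
    """
    profile = profile or PipelineProfile()
    ob, of = (oracle_labels or (None, None))
    seg_b = segment_scan(baseline, detector, refiner, profile, oracle_labels=ob)
    seg_f = segment_scan(followup, detector, refiner, profile, oracle_labels=of)
    if transform is None:
        transform = register_similarity(seg_b.normalized.volume, seg_f.normalized.volume)
    matches = match_lesions(seg_b.records, seg_f.records, transform)
    one_d, vol = assess_study_pair(
        seg_b.records, seg_f.records, matches, profile.max_targets, profile.min_diameter_mm
    )
    return PairAssessment(transform, matches, one_d, vol, seg_b, seg_f)


# -----------------------------------------------------------------------------
# ground-truth reference path
# -----------------------------------------------------------------------------

def truth_records(truth: ph.PhantomTruth) -> list[LesionRecord]:
    """Exact lesion records from generator ground truth (no measurement)."""
    records = []
    for lesion in truth.lesions:
        c = truth.lesion_center_world(lesion)
        r = truth.lesion_radii_world(lesion)
        vol = 4.0 / 3.0 * np.pi * float(np.prod(r))
        diam = float(2.0 * max(r[0], r[1]))
        z_half = float(r[2] / truth.spacing[2])
        cz = c[2] / truth.spacing[2]
        records.append(
            LesionRecord(lesion.id, 0, vol, diam, tuple(float(v) for v in c),
                         (int(np.floor(cz - z_half)), int(np.ceil(cz + z_half)) + 1))
        )
    return records


def truth_match_set(b_truth: ph.PhantomTruth, f_truth: ph.PhantomTruth) -> LesionMatchSet:
    """The generating correspondence between a phantom pair's lesions."""
    b_ids = {l.id for l in b_truth.lesions}
    f_ids = {l.id for l in f_truth.lesions}
    common = sorted(b_ids & f_ids)
    return LesionMatchSet(
        [(i, i, 0.0) for i in common],
        new=sorted(f_ids - b_ids),
        disappeared=sorted(b_ids - f_ids),
    )


def truth_assessment(
    b_truth: ph.PhantomTruth,
    f_truth: ph.PhantomTruth,
    min_diameter_mm: float = 5.0,
    max_targets: int = 5,
) -> tuple[ResponseAssessment, ResponseAssessment]:
    """Response categories implied by the exact generator geometry."""
    return assess_study_pair(
        truth_records(b_truth),
        truth_records(f_truth),
        truth_match_set(b_truth, f_truth),
        max_targets,
        min_diameter_mm,
    )


# -----------------------------------------------------------------------------
# cohorts
# -----------------------------------------------------------------------------

_SCENARIOS = ("CR", "PR", "SD", "PD", "PD_new")


def _scenario_changes(
    scenario: str, truth: ph.PhantomTruth, rng: np.random.Generator
) -> ph.FollowupChanges:
    ids = [l.id for l in truth.lesions]
    if scenario == "CR":
        return ph.FollowupChanges(removed=tuple(ids))
    if scenario == "PR":
        f = float(rng.uniform(0.55, 0.62))
        return ph.FollowupChanges(factors={i: f for i in ids})
    if scenario == "SD":
        f = float(rng.uniform(0.97, 1.05))
        return ph.FollowupChanges(factors={i: f for i in ids})
    if scenario == "PD":
        f = float(rng.uniform(1.30, 1.40))
        return ph.FollowupChanges(factors={i: f for i in ids})
    # PD by new lesion: sizes stable, one extra small enhancing nodule
    brain = truth.brain
    bc = np.asarray(brain.center_mm)
    br = np.asarray(brain.radii_mm)
    r_new = 1.5  # 3 mm lesion: below the measurability cutoff, still PD
    for _ in range(500):
        cand = bc + rng.uniform(-1, 1, size=3) * (br - r_new - 3.0)
        d = (cand - bc) / (br - r_new - 3.0)
        if d @ d > 1.0:
            continue
        if all(
            np.linalg.norm(cand - np.asarray(l.center_mm)) > 2.0 * (r_new + max(l.radii_mm)) + 3.0
            for l in truth.lesions
        ):
            new = ph.LesionSpec(0, tuple(float(v) for v in cand), (r_new, r_new, r_new), 2.5)
            return ph.FollowupChanges(added=(new,))
    raise RuntimeError("could not place the new lesion for a PD_new scenario")


def _moderate_transform(truth: ph.PhantomTruth, rng: np.random.Generator) -> SimilarityTransform:
    center = tuple(float(c) for c in truth.brain.center_mm)
    for _ in range(50):
        t = SimilarityTransform(
            tuple(rng.uniform(-5, 5, size=3)),
            tuple(rng.uniform(-3, 3, size=3)),
            float(rng.uniform(0.985, 1.015)),
            center,
        )
        try:
            ph._check_brain_inside(truth, t)
            return t
        except ValueError:
            continue
    return SimilarityTransform(center_mm=center)


def make_cohort(
    n_pairs: int,
    config: ph.PhantomConfig | None = None,
    seed: int = 0,
    scenarios: tuple[str, ...] = _SCENARIOS,
) -> list[dict]:
    """Generate a longitudinal phantom cohort with balanced change scenarios.

    Returns one dict per pair: baseline/followup (volume, labels, truth)
    triples plus the scenario tag and generating transform.
    """
    config = config or ph.PhantomConfig.tiny(diameter_range_mm=(6.0, 12.0))
    rng = np.random.default_rng(seed)
    cohort = []
    for k in range(n_pairs):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        b_vol, b_lab, b_truth = ph.generate_phantom(config, pair_seed)
        scenario = scenarios[k % len(scenarios)]
        changes = _scenario_changes(scenario, b_truth, rng)
        t = _moderate_transform(b_truth, rng)
        f_vol, f_lab, f_truth = ph.generate_followup(b_truth, t, changes, seed=pair_seed + 1)
        cohort.append(
            {
                "subject": f"sub{k:03d}",
                "scenario": scenario,
                "transform": t,
                "baseline": (b_vol, b_lab, b_truth),
                "followup": (f_vol, f_lab, f_truth),
            }
        )
    return cohort


def evaluate_cohort(
    cohort: list[dict],
    detector: MetastasisDetector3D | None = None,
    refiner: LesionRefiner2D | None = None,
    profile: PipelineProfile | None = None,
    oracle: bool = False,
    register: bool = True,
) -> dict:
    """Run the pipeline over a phantom cohort and score it against truth.

    Returns detection evals, per-lesion Dice, registration parameter
    errors, lesion-match success rate, and the 4x4 agreement (with kappas)
    between pipeline and truth response categories.
    """
    profile = profile or PipelineProfile.tiny()
    evals: list[DetectionEval] = []
    reg_errors = {"angle_deg": [], "translation_mm": [], "scale": []}
    match_sets, truth_pair_lists = [], []
    cats_1d, cats_vol, truth_1d, truth_vol = [], [], [], []
    per_pair = []
    for pair in cohort:
        b_vol, b_lab, b_truth = pair["baseline"]
        f_vol, f_lab, f_truth = pair["followup"]
        t_true = pair["transform"]
        res = assess_pair(
            b_vol, f_vol, detector, refiner, profile,
            oracle_labels=(b_lab, f_lab) if oracle else None,
            transform=None if register else t_true,
        )
        for seg, lab, truth in ((res.baseline, b_lab, b_truth), (res.followup, f_lab, f_truth)):
            evals.append(match_detections_to_truth(seg.labels, lab, truth.diameters_by_id()))
        if register:
            reg_errors["angle_deg"].append(
                float(np.max(np.abs(np.asarray(res.transform.angles_deg) - np.asarray(t_true.angles_deg))))
            )
            reg_errors["translation_mm"].append(
                float(np.max(np.abs(np.asarray(res.transform.translation_mm) - np.asarray(t_true.translation_mm))))
            )
            reg_errors["scale"].append(abs(res.transform.scale - t_true.scale))
        # lesion matching scored in truth id space via segmentation-truth overlap
        ms, tp = _truth_space_matches(res, b_lab, f_lab, b_truth, f_truth)
        match_sets.append(ms)
        truth_pair_lists.append(tp)
        t1, tv = truth_assessment(b_truth, f_truth, profile.min_diameter_mm, profile.max_targets)
        cats_1d.append(res.one_d.category)
        cats_vol.append(res.volumetric.category)
        truth_1d.append(t1.category)
        truth_vol.append(tv.category)
        per_pair.append({"subject": pair["subject"], "scenario": pair["scenario"],
                         "cad_1d": res.one_d.category, "truth_1d": t1.category,
                         "cad_vol": res.volumetric.category, "truth_vol": tv.category})
    mean_dice, sd_dice, n_dice = per_lesion_dice(evals, profile.min_diameter_mm)
    all_dice = [
        d for ev in evals for i, d in ev.dice_by_id.items() if ev.diameters_mm.get(i, 0) >= profile.min_diameter_mm
    ]
    n5 = sum(1 for ev in evals for i, h in ev.hits.items() if ev.diameters_mm.get(i, 0) >= 5.0)
    det5 = sum(h for ev in evals for i, h in ev.hits.items() if ev.diameters_mm.get(i, 0) >= 5.0)
    table_1d = ConfusionTable4.from_categories(cats_1d, truth_1d)
    table_vol = ConfusionTable4.from_categories(cats_vol, truth_vol)
    out = {
        "n_pairs": len(cohort),
        "sensitivity_ge5mm": det5 / n5 if n5 else float("nan"),
        "n_lesions_ge5mm": n5,
        "fp_per_scan": float(np.mean([ev.fp_count for ev in evals])),
        "mean_dice_ge5mm": mean_dice,
        "sd_dice_ge5mm": sd_dice,
        "min_dice_ge5mm": float(min(all_dice)) if all_dice else float("nan"),
        "n_dice": n_dice,
        "match_success_rate": registration_success_rate(match_sets, truth_pair_lists),
        "category_accuracy_1d": float(np.mean([a == b for a, b in zip(cats_1d, truth_1d)])),
        "category_accuracy_vol": float(np.mean([a == b for a, b in zip(cats_vol, truth_vol)])),
        "kappa_1d_vs_truth": _safe_kappa(table_1d),
        "kappa_vol_vs_truth": _safe_kappa(table_vol),
        "per_pair": per_pair,
        "agreement_table_1d": table_1d.counts.tolist(),
        "agreement_table_vol": table_vol.counts.tolist(),
    }
    if register:
        out["registration_error"] = {k: (float(np.max(v)) if v else float("nan")) for k, v in reg_errors.items()}
    return out


def _safe_kappa(table: ConfusionTable4) -> float:
    try:
        return weighted_kappa(table)
    except ValueError:
        return float("nan")


def _truth_space_matches(res: PairAssessment, b_lab, f_lab, b_truth, f_truth):
    """Re-express the pipeline's matched pairs in truth lesion ids.

    A segmented lesion inherits the truth id it overlaps most; pipeline
    pairs whose two members map to truth lesions give truth-space pairs
    comparable against the generating correspondence.
    """
    def id_map(seg_labels: LabelMap, truth_labels: LabelMap) -> dict[int, int]:
        m = {}
        for sid in seg_labels.ids:
            vals, counts = np.unique(truth_labels.labels[seg_labels.labels == sid], return_counts=True)
            fg = vals > 0
            if fg.any():
                m[sid] = int(vals[fg][np.argmax(counts[fg])])
        return m

    bmap = id_map(res.baseline.labels, b_lab)
    fmap = id_map(res.followup.labels, f_lab)
    pairs, seen_b, seen_f = [], set(), set()
    for b, f, r in res.matches.pairs:
        tb, tf = bmap.get(b), fmap.get(f)
        if tb is not None and tf is not None and tb not in seen_b and tf not in seen_f:
            pairs.append((tb, tf, r))
            seen_b.add(tb)
            seen_f.add(tf)
    ms = LesionMatchSet(pairs)
    truth_pairs = truth_match_set(b_truth, f_truth).pairs
    return ms, [(b, f) for b, f, _ in truth_pairs]


# -----------------------------------------------------------------------------
# training helpers
# -----------------------------------------------------------------------------

def build_training_data(
    n_volumes: int = 20,
    config: ph.PhantomConfig | None = None,
    profile: PipelineProfile | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Phantom training samples for both segmenters.

    Returns (cubes, binary cube labels, refiner patches, patch labels):
    normalized brain cubes with lesion masks for the detector, and axial
    patches cut around the true lesion boxes for the refiner.
    """
    config = config or ph.PhantomConfig.tiny()
    profile = profile or PipelineProfile.tiny()
    rng = np.random.default_rng(seed)
    cubes, cube_labels = [], []
    patches_x, patches_y = [], []
    for _ in range(n_volumes):
        s = int(rng.integers(0, 2**31 - 1))
        vol, lab, truth = ph.generate_phantom(config, s)
        mask = extract_brain_mask(vol)
        norm = normalize_intensity(vol, "auto", background_mask=~mask.mask())
        crop, crop_box = crop_to_brain(norm.volume, mask, profile.crop_margin_voxels)
        cube, record = resample_isotropic_cube(crop, profile.cube_size)
        truth_cube = record.resample_labels(lab.labels[crop_box.slices()])
        cubes.append(cube.data)
        cube_labels.append((truth_cube > 0).astype(np.float32))
        for cbox in extract_bounding_boxes(truth_cube, margin=profile.box_margin_cube):
            nbox = _shift_box(record.box_to_native(cbox), crop_box.lo, vol.shape)
            px = crop_and_upsample(norm.volume.data, nbox, profile.patch_size, profile.refine_margin_frac)
            py = crop_and_upsample((lab.labels > 0).astype(np.float32), nbox, profile.patch_size,
                                   profile.refine_margin_frac)
            for xp, yp in zip(px.patches, py.patches):
                yb = (yp >= 0.5).astype(np.float32)
                # keep all lesion-bearing slices and a third of the empty ones
                if yb.any() or rng.random() < 1 / 3:
                    patches_x.append(xp)
                    patches_y.append(yb)
    return cubes, cube_labels, patches_x, patches_y


def train_models_from_phantoms(
    n_volumes: int = 20,
    config: ph.PhantomConfig | None = None,
    profile: PipelineProfile | None = None,
    detector_config=None,
    refiner_config=None,
    seed: int = 0,
) -> tuple[MetastasisDetector3D, LesionRefiner2D]:
    """Generate a phantom training set and fit both segmenters."""
    from ._net import TrainConfig

    cubes, cube_labels, patches_x, patches_y = build_training_data(n_volumes, config, profile, seed)
    det_cfg = detector_config or TrainConfig.tiny(epochs=10, seed=seed, patches_per_volume=8)
    ref_cfg = refiner_config or TrainConfig.tiny(epochs=2, seed=seed)
    detector = MetastasisDetector3D(train_config=det_cfg).fit(cubes, cube_labels)
    refiner = LesionRefiner2D(train_config=ref_cfg).fit(patches_x, patches_y)
    return detector, refiner
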
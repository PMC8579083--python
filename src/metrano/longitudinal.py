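"""Serial-scan registration and lesion-level matching.

Baseline and follow-up head scans of one patient are aligned with a
similarity transform — rotation, translation and one isotropic scale, the
three parameter groups that cover patient repositioning plus minor
calibration differences (a ``rigid=True`` flag freezes scale at 1). The
optimization maximizes image similarity (mean squared difference by
default, suited to same-modality serial scans) over a multi-resolution
pyramid.

Lesions are then matched one-to-one: baseline centroids are mapped through
the transform and assigned to follow-up centroids by minimal total
distance (Hungarian algorithm), gated by a distance threshold. Unmatched
follow-up lesions are "new"; unmatched baseline lesions "disappeared".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .quantify import LesionRecord
from .transform import SimilarityTransform
from .volio import Volume3D

__all__ = [
    "SimilarityTransform",
    "LesionMatchSet",
    "RegistrationError",
    "register_similarity",
    "match_lesions",
    "registration_success_rate",
]


class RegistrationError(RuntimeError):
    pass


def _to_sitk(vol: Volume3D) -> sitk.Image:
    # package convention is (x, y, z); SimpleITK's array interface is (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T.astype(np.float32)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _mask_centroid_world(vol: Volume3D) -> tuple[float, float, float]:
    idx = np.argwhere(vol.data > 0)
    if len(idx) == 0:
        idx = np.array([[s / 2 for s in vol.shape]])
    c = np.asarray(vol.origin) + idx.mean(axis=0) * np.asarray(vol.spacing)
    return tuple(float(v) for v in c)


def register_similarity(
    fixed: Volume3D,
    moving: Volume3D,
    metric: str = "msd",
    rigid: bool = False,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0),
    sampling_fraction: float = 0.25,
    seed: int = 12345,
    full_output: bool = False,
):
    """Estimate the similarity transform mapping fixed-scan points onto the
    moving scan by iterative multi-resolution optimization.

    Both volumes should be normalized and brain-masked (zero background)
    and share voxel spacing. Raises :class:`RegistrationError` when the
    optimizer fails to improve the similarity metric.
    """
    if not np.allclose(fixed.spacing, moving.spacing, rtol=1e-6):
        raise ValueError(
            f"spacing mismatch {fixed.spacing} vs {moving.spacing}: resample one scan first"
        )
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    center = _mask_centroid_world(fixed)

    initial = sitk.Similarity3DTransform()
    initial.SetCenter(center)

    reg = sitk.ImageRegistrationMethod()
    if metric == "msd":
        reg.SetMetricAsMeanSquares()
    elif metric in ("mi", "mutual_information"):
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(sampling_fraction, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-6, numberOfIterations=500, relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-10,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)

    if rigid:
        # freeze the scale parameter (last of the 7) at 1
        reg.SetOptimizerWeights([1, 1, 1, 1, 1, 1, 0])

    metric_trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: metric_trace.append(reg.GetMetricValue()))
    # regular sampling probes a few points just outside the moving buffer,
    # which ITK reports noisily; those samples are simply skipped
    sitk.ProcessObject_SetGlobalWarningDisplay(False)
    try:
        fitted = reg.Execute(f_img, m_img)
    except RuntimeError as err:
        raise RegistrationError(f"registration failed: {err}") from err
    finally:
        sitk.ProcessObject_SetGlobalWarningDisplay(True)

    final_metric = float(reg.GetMetricValue())
    identity_metric = _metric_value(f_img, m_img, sitk.Similarity3DTransform(), metric, center)
    if metric_trace and final_metric > identity_metric * (1.0 + 1e-6) and metric == "msd":
        raise RegistrationError(
            f"optimizer diverged: final metric {final_metric:.4g} worse than identity "
            f"{identity_metric:.4g}; trace tail {metric_trace[-5:]}"
        )

    sim = sitk.Similarity3DTransform(fitted)
    M = np.asarray(sim.GetMatrix()).reshape(3, 3)
    s = float(np.linalg.det(M) ** (1.0 / 3.0))
    angles = Rotation.from_matrix(M / s).as_euler("xyz", degrees=True)
    out = SimilarityTransform(tuple(angles), tuple(sim.GetTranslation()), s, tuple(sim.GetCenter()))
    if full_output:
        info = {
            "final_metric": final_metric,
            "identity_metric": identity_metric,
            "converged": final_metric <= identity_metric + 1e-12,
            "stop_condition": reg.GetOptimizerStopConditionDescription(),
            "n_iterations": len(metric_trace),
        }
        return out, info
    return out


def _metric_value(f_img, m_img, transform, metric, center) -> float:
    transform.SetCenter(center)
    reg = sitk.ImageRegistrationMethod()
    if metric == "msd":
        reg.SetMetricAsMeanSquares()
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(transform)
    return float(reg.MetricEvaluate(f_img, m_img))


@dataclass
class LesionMatchSet:
    """Outcome of baseline/follow-up lesion matching."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (baseline id, follow-up id, residual mm)
    new: list[int] = field(default_factory=list)
    disappeared: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        b_ids = [p[0] for p in self.pairs]
        f_ids = [p[1] for p in self.pairs]
        if len(set(b_ids)) != len(b_ids) or len(set(f_ids)) != len(f_ids):
            raise ValueError("each lesion id may appear in at most one pair")
        if set(self.new) & set(f_ids) or set(self.disappeared) & set(b_ids):
            raise ValueError("new/disappeared ids must be disjoint from matched pairs")

    @property
    def matched_baseline_ids(self) -> set[int]:
        return {p[0] for p in self.pairs}

    def followup_of(self, baseline_id: int) -> int | None:
        for b, f, _ in self.pairs:
            if b == baseline_id:
                return f
        return None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"baseline_id": b, "followup_id": f, "residual_mm": r, "status": "matched"} for b, f, r in self.pairs
        ]
        rows += [{"baseline_id": None, "followup_id": f, "residual_mm": None, "status": "new"} for f in self.new]
        rows += [
            {"baseline_id": b, "followup_id": None, "residual_mm": None, "status": "disappeared"}
            for b in self.disappeared
        ]
        return pd.DataFrame(rows, columns=["baseline_id", "followup_id", "residual_mm", "status"])


def match_lesions(
    baseline: list[LesionRecord],
    followup: list[LesionRecord],
    transform: SimilarityTransform,
    tolerance_mm: float = 5.0,
) -> LesionMatchSet:
    """One-to-one lesion correspondence across a registered scan pair.

    Baseline centroids are mapped through ``transform``; candidate pairs
    within ``max(tolerance_mm, r_b + r_f)`` (equivalent-sphere radii) are
    assigned by minimal total distance.
    """
    if not baseline and not followup:
        return LesionMatchSet()
    if not baseline:
        return LesionMatchSet(new=[r.id for r in followup])
    if not followup:
        return LesionMatchSet(disappeared=[r.id for r in baseline])
    b_pts = transform.apply(np.asarray([r.centroid_mm for r in baseline]))
    f_pts = np.asarray([r.centroid_mm for r in followup])
    dist = np.linalg.norm(b_pts[:, None, :] - f_pts[None, :, :], axis=-1)
    gate = np.maximum(
        tolerance_mm,
        np.asarray([r.equivalent_radius_mm for r in baseline])[:, None]
        + np.asarray([r.equivalent_radius_mm for r in followup])[None, :],
    )
    allowed = dist < gate
    BIG = 1e9
    cost = np.where(allowed, dist, BIG)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (baseline[i].id, followup[j].id, float(dist[i, j])) for i, j in zip(rows, cols) if allowed[i, j]
    ]
    matched_b = {p[0] for p in pairs}
    matched_f = {p[1] for p in pairs}
    return LesionMatchSet(
        pairs,
        new=[r.id for r in followup if r.id not in matched_f],
        disappeared=[r.id for r in baseline if r.id not in matched_b],
    )


def registration_success_rate(
    match_sets: list[LesionMatchSet],
    truth_pairs: list[list[tuple[int, int]]],
) -> float:
    """Fraction of true baseline/follow-up lesion correspondences recovered.

    ``truth_pairs[k]`` lists the true (baseline id, follow-up id) pairs of
    cohort member ``k``.
    """
    if not match_sets:
        raise ValueError("empty cohort")
    if len(match_sets) != len(truth_pairs):
        raise ValueError("one truth pair list required per match set")
    total = sum(len(tp) for tp in truth_pairs)
    if total == 0:
        raise ValueError("no true correspondences in cohort")
    hit = 0
    for ms, tp in zip(match_sets, truth_pairs):
        found = {(b, f) for b, f, _ in ms.pairs}
        hit += sum(1 for pair in tp if pair in found)
    return hit / total
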
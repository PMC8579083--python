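"""Automated treatment-response categorization (modified RANO-BM).

Up to five target lesions — the largest measurable lesions, where
"measurable" is a longest axial diameter of at least 5 mm (the modified
cutoff appropriate for 1 mm-slice 3D imaging) — are selected on the
baseline scan, and the sum of their longest diameters is compared with the
follow-up sum over the same (matched) lesions:

* any new lesion, regardless of size  -> PD
* follow-up sum 0 (all targets gone)  -> CR
* decrease >= 30%                     -> PR
* increase >= 20%                     -> PD
* otherwise                           -> SD

Boundary values are inclusive. The volumetric variant applies the same
logic to total target volume with the 1D thresholds cubed (PR at ratio
<= 0.7³ = 0.343, PD at >= 1.2³ = 1.728), so an isotropic diameter change
maps to the same category on both bases. Both threshold sets are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .longitudinal import LesionMatchSet
from .quantify import LesionRecord

__all__ = [
    "CATEGORIES",
    "TargetSet",
    "ResponseAssessment",
    "select_target_lesions",
    "assess_response_1d",
    "assess_response_volumetric",
    "assess_study_pair",
]

CATEGORIES = ("CR", "PR", "SD", "PD")

PR_THRESHOLD_1D = -0.30  # relative change in diameter sum
PD_THRESHOLD_1D = 0.20
PR_RATIO_VOL = 0.343  # = 0.70**3
PD_RATIO_VOL = 1.728  # = 1.20**3


@dataclass
class TargetSet:
    """Up to five measurable target lesions, sorted by diameter descending."""

    records: list[LesionRecord]
    min_diameter_mm: float = 5.0
    max_n: int = 5

    def __post_init__(self) -> None:
        if len(self.records) > self.max_n:
            raise ValueError(f"target set limited to {self.max_n} lesions")
        if any(r.longest_axial_diameter_mm < self.min_diameter_mm for r in self.records):
            raise ValueError("every target lesion must meet the measurability threshold")
        diams = [r.longest_axial_diameter_mm for r in self.records]
        if diams != sorted(diams, reverse=True):
            raise ValueError("target lesions must be sorted by diameter descending")

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.records]

    @property
    def sum_longest_diameters_mm(self) -> float:
        return sum(r.longest_axial_diameter_mm for r in self.records)

    @property
    def total_volume_mm3(self) -> float:
        return sum(r.volume_mm3 for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ResponseAssessment:
    """One CR/PR/SD/PD call with the numbers behind it."""

    category: str
    basis: str  # "one-dimensional" | "volumetric"
    baseline_sum: float
    followup_sum: float
    new_lesion: bool
    target_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    @property
    def percent_change(self) -> float:
        if self.baseline_sum == 0:
            return float("nan")
        return 100.0 * (self.followup_sum - self.baseline_sum) / self.baseline_sum

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "category": self.category,
            "baseline_sum": self.baseline_sum,
            "followup_sum": self.followup_sum,
            "pct_change": self.percent_change,
            "new_lesion": self.new_lesion,
            "target_ids": list(self.target_ids),
        }


def select_target_lesions(
    records: list[LesionRecord], max_n: int = 5, min_diameter_mm: float = 5.0
) -> TargetSet:
    """Pick the up-to-``max_n`` largest measurable lesions.

    Sorting is by diameter descending, ties broken by volume descending
    then id ascending. An empty target set is allowed.
    """
    measurable = [r for r in records if r.longest_axial_diameter_mm >= min_diameter_mm]
    measurable.sort(key=lambda r: (-r.longest_axial_diameter_mm, -r.volume_mm3, r.id))
    return TargetSet(measurable[:max_n], min_diameter_mm, max_n)


def assess_response_1d(
    baseline: TargetSet,
    followup_sum_mm: float,
    new_lesion: bool,
    pr_threshold: float = PR_THRESHOLD_1D,
    pd_threshold: float = PD_THRESHOLD_1D,
) -> ResponseAssessment:
    """Categorize by change in the sum of longest diameters.

    ``followup_sum_mm`` is the diameter sum over follow-up lesions matched
    to the baseline targets (disappeared targets contribute 0).
    """
    if len(baseline) == 0:
        raise ValueError("response is undefined for an empty baseline target set")
    s_b = baseline.sum_longest_diameters_mm
    if new_lesion:
        cat = "PD"
    elif followup_sum_mm == 0:
        cat = "CR"
    else:
        delta = (followup_sum_mm - s_b) / s_b
        if delta <= pr_threshold:
            cat = "PR"
        elif delta >= pd_threshold:
            cat = "PD"
        else:
            cat = "SD"
    return ResponseAssessment(cat, "one-dimensional", s_b, followup_sum_mm, new_lesion, baseline.ids)


def assess_response_volumetric(
    baseline_volume_mm3: float,
    followup_volume_mm3: float,
    new_lesion: bool,
    pr_ratio: float = PR_RATIO_VOL,
    pd_ratio: float = PD_RATIO_VOL,
    target_ids: list[int] | None = None,
) -> ResponseAssessment:
    """Categorize by the ratio of total target volumes."""
    if baseline_volume_mm3 <= 0:
        raise ValueError("baseline target volume must be positive")
    if new_lesion:
        cat = "PD"
    elif followup_volume_mm3 == 0:
        cat = "CR"
    else:
        ratio = followup_volume_mm3 / baseline_volume_mm3
        if ratio <= pr_ratio:
            cat = "PR"
        elif ratio >= pd_ratio:
            cat = "PD"
        else:
            cat = "SD"
    return ResponseAssessment(
        cat, "volumetric", baseline_volume_mm3, followup_volume_mm3, new_lesion, target_ids or []
    )


def assess_study_pair(
    baseline_records: list[LesionRecord],
    followup_records: list[LesionRecord],
    matches: LesionMatchSet,
    max_n: int = 5,
    min_diameter_mm: float = 5.0,
) -> tuple[ResponseAssessment, ResponseAssessment]:
    """Full response assessment of one baseline/follow-up pair.

    Targets are selected on baseline and tracked forward through
    ``matches`` (no re-selection on follow-up); the new-lesion flag is set
    when any unmatched follow-up lesion exists.
    """
    targets = select_target_lesions(baseline_records, max_n, min_diameter_mm)
    by_id = {r.id: r for r in followup_records}
    s_f = 0.0
    v_f = 0.0
    for b_id in targets.ids:
        f_id = matches.followup_of(b_id)
        if f_id is not None and f_id in by_id:
            s_f += by_id[f_id].longest_axial_diameter_mm
            v_f += by_id[f_id].volume_mm3
    new_lesion = len(matches.new) > 0
    one_d = assess_response_1d(targets, s_f, new_lesion)
    vol = assess_response_volumetric(targets.total_volume_mm3, v_f, new_lesion, target_ids=targets.ids)
    return one_d, vol
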
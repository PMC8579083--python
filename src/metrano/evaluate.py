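"""Detection, segmentation and agreement metrics.

Lesion-wise counting: a ground-truth lesion is *detected* when at least
one predicted voxel overlaps it; a predicted component overlapping no
truth lesion is one false positive. Sensitivity is reported overall, for
lesions >= 5 mm, and per size bin. Segmentation quality is the Dice
similarity coefficient per matched lesion. Agreement between two ordered
CR/PR/SD/PD assessments uses Cohen's weighted kappa (linear weights by
default), and binomial proportions carry exact Clopper-Pearson 95%
intervals (Wilson score available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volio import LabelMap

__all__ = [
    "DetectionEval",
    "ConfusionTable4",
    "match_detections_to_truth",
    "sensitivity_by_size",
    "dice_coefficient",
    "per_lesion_dice",
    "weighted_kappa",
    "kappa_agreement_category",
    "proportion_ci",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DetectionEval:
    """Lesion-wise detection outcome for one scan."""

    hits: dict[int, bool]  # truth lesion id -> detected
    fp_count: int
    diameters_mm: dict[int, float] = field(default_factory=dict)
    dice_by_id: dict[int, float] = field(default_factory=dict)

    @property
    def n_truth(self) -> int:
        return len(self.hits)

    @property
    def n_detected(self) -> int:
        return sum(self.hits.values())

    def sensitivity(self, min_diameter_mm: float = 0.0) -> float | None:
        ids = [i for i in self.hits if self.diameters_mm.get(i, np.inf) >= min_diameter_mm]
        if not ids:
            return None
        return sum(self.hits[i] for i in ids) / len(ids)


def _as_labels(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelMap) else np.asarray(x)


def match_detections_to_truth(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    diameters_mm: dict[int, float] | None = None,
) -> DetectionEval:
    """Count hits and false positives on one scan.

    ``pred`` and ``truth`` are labeled component maps on the same grid.
    Per-truth-lesion Dice is computed against the union of predicted
    components whose largest overlap is with that lesion.
    """
    p = _as_labels(pred)
    t = _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    truth_ids = [int(v) for v in np.unique(t) if v > 0]
    pred_ids = [int(v) for v in np.unique(p) if v > 0]
    hits = {tid: bool(np.any(p[t == tid] > 0)) for tid in truth_ids}
    # assign each predicted component to the truth lesion it overlaps most
    assignment: dict[int, int] = {}
    fp = 0
    for pid in pred_ids:
        overlap_labels, counts = np.unique(t[p == pid], return_counts=True)
        fg = overlap_labels > 0
        if not fg.any():
            fp += 1
            continue
        assignment[pid] = int(overlap_labels[fg][np.argmax(counts[fg])])
    dice_by_id = {}
    for tid in truth_ids:
        if not hits[tid]:
            continue
        pred_union = np.isin(p, [pid for pid, a in assignment.items() if a == tid])
        dice_by_id[tid] = dice_coefficient(pred_union, t == tid)
    return DetectionEval(hits, fp, dict(diameters_mm or {}), dice_by_id)


def sensitivity_by_size(
    evals: list[DetectionEval],
    bin_edges_mm: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0, 20.0, np.inf),
) -> pd.DataFrame:
    """Per-size-bin lesion counts and sensitivity, plus the >= 5 mm aggregate.

    Bins are half-open ``[lo, hi)``; empty bins report NA sensitivity.
    """
    edges = list(bin_edges_mm)
    if edges != sorted(edges) or len(edges) < 2:
        raise ValueError("bin edges must be increasing")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = det = 0
        for ev in evals:
            for tid, hit in ev.hits.items():
                d = ev.diameters_mm.get(tid)
                if d is not None and lo <= d < hi:
                    n += 1
                    det += hit
        rows.append({"lo_mm": lo, "hi_mm": hi, "n": n, "detected": det,
                     "sensitivity": det / n if n else np.nan})
    n5 = det5 = 0
    for ev in evals:
        for tid, hit in ev.hits.items():
            d = ev.diameters_mm.get(tid)
            if d is not None and d >= 5.0:
                n5 += 1
                det5 += hit
    rows.append({"lo_mm": 5.0, "hi_mm": np.inf, "n": n5, "detected": det5,
                 "sensitivity": det5 / n5 if n5 else np.nan})
    return pd.DataFrame(rows)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient ``2|P∩T| / (|P| + |T|)``."""
    p = np.asarray(pred) > 0
    t = np.asarray(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("empty truth mask")
    return 2.0 * np.logical_and(p, t).sum() / (p.sum() + t.sum())


def per_lesion_dice(evals: list[DetectionEval], min_diameter_mm: float = 0.0) -> tuple[float, float, int]:
    """Cohort mean ± SD Dice over detected lesions; returns (mean, sd, n)."""
    values = []
    for ev in evals:
        for tid, d in ev.dice_by_id.items():
            if ev.diameters_mm.get(tid, np.inf) >= min_diameter_mm:
                values.append(d)
    if not values:
        return float("nan"), float("nan"), 0
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0, len(values)


@dataclass
class ConfusionTable4:
    """4x4 CR/PR/SD/PD counts; rows = automated call, columns = ground truth."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4, 4):
            raise ValueError("expected a 4x4 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_categories(cls, rated: list[str], truth: list[str]) -> "ConfusionTable4":
        order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}
        counts = np.zeros((4, 4))
        for a, b in zip(rated, truth):
            counts[order[a], order[b]] += 1
        return cls(counts)


def weighted_kappa(table: ConfusionTable4 | np.ndarray, weights: str = "linear") -> float:
    """Cohen's weighted kappa for ordered categories.

    Linear agreement weights ``w_ij = 1 - |i-j|/(k-1)`` by default;
    ``weights="quadratic"`` squares the distance term.
    """
    counts = table.counts if isinstance(table, ConfusionTable4) else np.asarray(table, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    k = counts.shape[0]
    i, j = np.indices(counts.shape)
    if weights == "linear":
        w = 1.0 - np.abs(i - j) / (k - 1)
    elif weights == "quadratic":
        w = 1.0 - ((i - j) / (k - 1)) ** 2
    elif weights == "identity":
        w = (i == j).astype(float)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    p_o = (w * counts).sum() / n
    p_e = (w * np.outer(counts.sum(axis=1), counts.sum(axis=0))).sum() / n**2
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_agreement_category(kappa: float) -> str:
    """Conventional verbal label for a kappa value."""
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def proportion_ci(
    successes: int, trials: int, confidence: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Two-sided binomial CI for a proportion, returned in percent.

    Exact Clopper-Pearson by default; ``method="wilson"`` gives the Wilson
    score interval.
    """
    if trials <= 0 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - confidence
    x, n = successes, trials
    if method == "clopper-pearson":
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    elif method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        phat = x / n
        denom = 1 + z**2 / n
        center = (phat + z**2 / (2 * n)) / denom
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        lo, hi = max(0.0, center - half), min(1.0, center + half)
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * lo, 100.0 * hi
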
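"""Per-lesion fine segmentation.

Each detected bounding box is expanded by a safety margin, its axial
slices are upsampled to a large square patch (default 512x512, aspect
ratio preserved via zero padding) so even small metastases span many
pixels, a 2D encoder-decoder segments every patch, and the thresholded
results are mapped back to the native grid and unioned in 3D.

Patch geometry is recorded exactly, so the patch -> native mapping is a
closed form with no drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._net import SegNet, TrainConfig
from .detect import label_components
from .volio import BoundingBox, LabelMap, Volume3D

__all__ = [
    "PatchRecord",
    "LesionPatchSet",
    "crop_and_upsample",
    "LesionRefiner2D",
    "refine_lesion",
    "assemble_lesion_map",
]


@dataclass(frozen=True)
class PatchRecord:
    """Geometry of one axial patch: native in-plane box at slice ``z``,
    one in-plane scale, and centering offsets inside the patch."""

    z: int
    lo: tuple[int, int]  # in-plane native box, half-open
    hi: tuple[int, int]
    scale: float  # patch pixels per native voxel
    offset: tuple[int, int]
    patch_size: int

    def patch_coords_of_native(self, i: np.ndarray, j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = (np.asarray(i, float) - self.lo[0] + 0.5) * self.scale - 0.5 + self.offset[0]
        v = (np.asarray(j, float) - self.lo[1] + 0.5) * self.scale - 0.5 + self.offset[1]
        return u, v

    def native_coords_of_patch(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = (np.asarray(u, float) - self.offset[0] + 0.5) / self.scale - 0.5 + self.lo[0]
        j = (np.asarray(v, float) - self.offset[1] + 0.5) / self.scale - 0.5 + self.lo[1]
        return i, j


@dataclass
class LesionPatchSet:
    """Axial patch stack for one candidate lesion with exact geometry."""

    patches: np.ndarray  # (n_slices, P, P) float32
    records: list[PatchRecord]
    box: BoundingBox  # margin-expanded native box the patches cover

    def __post_init__(self) -> None:
        if len(self.records) != self.patches.shape[0]:
            raise ValueError("one geometric record required per patch")


def _expand_box(box: BoundingBox, grid_shape, margin_frac: float, min_size: int = 8) -> BoundingBox:
    lo, hi = list(box.lo), list(box.hi)
    for ax in range(3):
        size = hi[ax] - lo[ax]
        m = int(round(margin_frac * size))
        if margin_frac > 0:
            m = max(1, m)
        lo[ax] -= m
        hi[ax] += m
        while hi[ax] - lo[ax] < min_size:  # degenerate box: pad to minimum
            lo[ax] -= 1
            hi[ax] += 1
        lo[ax] = max(0, lo[ax])
        hi[ax] = min(grid_shape[ax], hi[ax])
    return BoundingBox(tuple(lo), tuple(hi))


def crop_and_upsample(
    vol: Volume3D | np.ndarray,
    box: BoundingBox,
    patch_size: int = 512,
    margin_frac: float = 0.25,
) -> LesionPatchSet:
    """Cut the margin-expanded box and upsample each axial slice to a square
    patch, preserving the in-plane aspect ratio with zero padding."""
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    if not BoundingBox((0, 0, 0), data.shape).contains_box(box):
        raise ValueError(f"box {box} outside grid {data.shape}")
    ebox = _expand_box(box, data.shape, margin_frac)
    bx, by = ebox.hi[0] - ebox.lo[0], ebox.hi[1] - ebox.lo[1]
    scale = patch_size / max(bx, by)
    cx, cy = int(round(bx * scale)), int(round(by * scale))
    cx, cy = min(cx, patch_size), min(cy, patch_size)
    off = ((patch_size - cx) // 2, (patch_size - cy) // 2)
    patches, records = [], []
    uu, vv = np.meshgrid(np.arange(patch_size), np.arange(patch_size), indexing="ij")
    for z in range(ebox.lo[2], ebox.hi[2]):
        rec = PatchRecord(z, (ebox.lo[0], ebox.lo[1]), (ebox.hi[0], ebox.hi[1]), scale, off, patch_size)
        i, j = rec.native_coords_of_patch(uu, vv)
        patch = ndimage.map_coordinates(
            data[:, :, z].astype(np.float32), [i, j], order=1, mode="constant", cval=0.0
        )
        # zero out pixels mapping outside the native box (padding region)
        inside = (i >= rec.lo[0] - 0.5) & (i < rec.hi[0] - 0.5) & (j >= rec.lo[1] - 0.5) & (j < rec.hi[1] - 0.5)
        patch[~inside] = 0.0
        patches.append(patch)
        records.append(rec)
    return LesionPatchSet(np.stack(patches), records, ebox)


_DIHEDRAL_SHIFTS = [(0, 0), (2, -2)]


def sixteen_fold(x: np.ndarray, y: np.ndarray):
    """The 16 flip/rotation/translation variants of one patch pair."""
    out = []
    for k in range(4):
        for flip in (False, True):
            xi = np.rot90(x, k)
            yi = np.rot90(y, k)
            if flip:
                xi, yi = np.flip(xi, 0), np.flip(yi, 0)
            for sh in _DIHEDRAL_SHIFTS:
                out.append(
                    (np.ascontiguousarray(np.roll(xi, sh, (0, 1))), np.ascontiguousarray(np.roll(yi, sh, (0, 1))))
                )
    return out


class LesionRefiner2D(BaseEstimator):
    """2D encoder-decoder fine segmenter (scikit-learn style estimator).

    Trains on axial lesion patches; when ``train_config.augment`` is on the
    training set is expanded 16-fold with flip/rotation/translation
    variants. A pretrained encoder is not used: weights start from a seeded
    random initialization.

    Attributes
    ----------
    net_ : SegNet
    loss_history_ : dict
    """

    def __init__(self, base_channels: int = 8, kernel: int = 3, threshold: float = 0.5,
                 train_config: TrainConfig | None = None):
        self.base_channels = base_channels
        self.kernel = kernel
        self.threshold = threshold
        self.train_config = train_config

    def fit(self, X: list[np.ndarray], y: list[np.ndarray]) -> "LesionRefiner2D":
        if len(X) < 2:
            raise ValueError("need at least 2 training patches")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        cfg = self.train_config or TrainConfig()
        samples = [(np.asarray(a, np.float32), (np.asarray(b) > 0).astype(np.float32)) for a, b in zip(X, y)]
        if cfg.augment:
            samples = [pair for s in samples for pair in sixteen_fold(*s)]
        self.net_ = SegNet(2, self.base_channels, self.kernel, seed=cfg.seed)
        self.loss_history_ = self.net_.fit(samples, cfg, augment_fn=None)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("refiner is not fitted")
        return self.net_.predict_proba(np.asarray(X, np.float32))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def save(self, path) -> None:
        self.net_.save(path)

    @classmethod
    def load(cls, path, **params) -> "LesionRefiner2D":
        est = cls(**params)
        est.net_ = SegNet.load(path)
        est.loss_history_ = {}
        est.base_channels = est.net_.base_channels
        est.kernel = est.net_.kernel
        return est


def refine_lesion(
    patches: LesionPatchSet,
    model,
    grid_shape: tuple[int, int, int],
    threshold: float = 0.5,
) -> np.ndarray:
    """Segment every patch, map back to the native grid, and union slices.

    Returns a boolean mask on the full native grid. An all-background
    prediction yields an empty mask — the refiner may veto a detection.
    """
    mask = np.zeros(grid_shape, dtype=bool)
    for patch, rec in zip(patches.patches, patches.records):
        prob = np.asarray(model.predict_proba(patch))
        if prob.shape != patch.shape:
            raise ValueError("geometry record mismatch: model output shape differs from patch")
        binary = prob >= threshold
        if not binary.any():
            continue
        ii, jj = np.meshgrid(np.arange(rec.lo[0], rec.hi[0]), np.arange(rec.lo[1], rec.hi[1]), indexing="ij")
        u, v = rec.patch_coords_of_native(ii, jj)
        u = np.clip(np.rint(u).astype(int), 0, rec.patch_size - 1)
        v = np.clip(np.rint(v).astype(int), 0, rec.patch_size - 1)
        mask[rec.lo[0] : rec.hi[0], rec.lo[1] : rec.hi[1], rec.z] |= binary[u, v]
    return mask


def assemble_lesion_map(
    masks: list[np.ndarray],
    grid_shape: tuple[int, int, int],
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> LabelMap:
    """Voxelwise OR of per-lesion masks, relabeled by 26-connectivity."""
    union = np.zeros(grid_shape, dtype=bool)
    for m in masks:
        if m.shape != tuple(grid_shape):
            raise ValueError(f"mask shape {m.shape} != grid {grid_shape}")
        union |= m.astype(bool)
    return LabelMap(label_components(union), spacing, origin)
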
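"""Coarse 3D lesion localization on the isotropic cube.

A 3D encoder-decoder segmenter trained under the Dice loss finds candidate
metastases in the whole brain at once; its thresholded probability map is
split into 26-connected components whose bounding boxes seed the fine
per-lesion segmentation stage.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._net import SegNet, TrainConfig, soft_dice_loss
from .volio import BoundingBox, LabelMap

__all__ = [
    "TrainConfig",
    "dice_loss",
    "MetastasisDetector3D",
    "detect_lesions",
    "label_components",
    "extract_bounding_boxes",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-7) -> float:
    """Dice loss ``1 - 2*sum(pred*truth) / (sum(pred) + sum(truth) + eps)``.

    ``pred`` is a probability grid in [0, 1], ``truth`` binary; the loss is
    symmetric in its arguments for binary inputs and bounded in [0, 1].
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.min() < -1e-9 or pred.max() > 1 + 1e-9:
        raise ValueError("pred must be a probability grid in [0, 1]")
    return soft_dice_loss(pred, truth, eps)[0]


def _augment3d(x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Random flip / 90-degree rotation / integer translation / mild scale."""
    for ax in range(3):
        if rng.random() < 0.5:
            x, y = np.flip(x, ax), np.flip(y, ax)
    k = int(rng.integers(4))
    if k:
        x, y = np.rot90(x, k, axes=(0, 1)), np.rot90(y, k, axes=(0, 1))
    shift = rng.integers(-2, 3, size=3)
    if np.any(shift):
        x = np.roll(x, shift, axis=(0, 1, 2))
        y = np.roll(y, shift, axis=(0, 1, 2))
    if rng.random() < 0.25:  # mild intensity scale, label untouched
        x = np.clip(x * rng.uniform(0.9, 1.1), 0.0, 1.0)
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


class MetastasisDetector3D(BaseEstimator):
    """3D encoder-decoder lesion detector (scikit-learn style estimator).

    Parameters
    ----------
    base_channels : int
        Width of the first encoder level.
    kernel : int
        Convolution kernel size.
    threshold : float
        Probability cutoff applied to the output map.
    min_voxels : int
        Components smaller than this are discarded as noise.
    train_config : TrainConfig or None
        Optimization settings; defaults to ``TrainConfig()``.

    Attributes
    ----------
    net_ : SegNet
        Trained network.
    loss_history_ : dict
        Per-epoch train/validation Dice loss.
    """

    def __init__(self, base_channels: int = 8, kernel: int = 3, threshold: float = 0.5,
                 min_voxels: int = 2, train_crop: int | None = 32, train_config: TrainConfig | None = None):
        self.base_channels = base_channels
        self.kernel = kernel
        self.threshold = threshold
        self.min_voxels = min_voxels
        self.train_crop = train_crop
        self.train_config = train_config

    def fit(self, X: list[np.ndarray], y: list[np.ndarray]) -> "MetastasisDetector3D":
        """Train on normalized cubes ``X`` with binary lesion masks ``y``.

        Each optimization step sees a random sub-cube (``train_crop`` per
        side, biased toward lesion locations) of an augmented volume: the
        network is fully convolutional, so small-crop training transfers to
        whole-cube prediction while giving many cheap updates per epoch.
        """
        if len(X) < 2:
            raise ValueError("need at least 2 training volumes")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        cfg = self.train_config or TrainConfig()
        samples = [(np.asarray(xi, np.float32), (np.asarray(yi) > 0).astype(np.float32)) for xi, yi in zip(X, y)]
        crop = self.train_crop

        def sample_fn(x, y_, rng):
            if cfg.augment:
                x, y_ = _augment3d(x, y_, rng)
            if crop is None or any(s <= crop for s in x.shape):
                return x, y_
            if rng.random() < 0.7 and y_.any():  # lesion-biased center
                c = np.argwhere(y_ > 0)[rng.integers(np.count_nonzero(y_ > 0))]
            else:
                c = rng.integers(0, x.shape[0], size=3)
            lo = np.clip(np.asarray(c) - crop // 2, 0, np.asarray(x.shape) - crop)
            sl = tuple(slice(int(a), int(a) + crop) for a in lo)
            return np.ascontiguousarray(x[sl]), np.ascontiguousarray(y_[sl])

        self.net_ = SegNet(3, self.base_channels, self.kernel, seed=cfg.seed)
        self.loss_history_ = self.net_.fit(samples, cfg, augment_fn=sample_fn)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Voxelwise lesion probability map for one cube."""
        if not hasattr(self, "net_"):
            raise RuntimeError("detector is not fitted")
        return self.net_.predict_proba(np.asarray(X, np.float32))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary lesion mask for one cube."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def save(self, path) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("detector is not fitted")
        self.net_.save(path)

    @classmethod
    def load(cls, path, **params) -> "MetastasisDetector3D":
        est = cls(**params)
        est.net_ = SegNet.load(path)
        est.loss_history_ = {}
        est.base_channels = est.net_.base_channels
        est.kernel = est.net_.kernel
        return est


def label_components(mask: np.ndarray, min_voxels: int = 1) -> np.ndarray:
    """26-connected component labeling with small-component removal.

    Labels are renumbered contiguously from 1 in scan order.
    """
    labels, n = ndimage.label(np.asarray(mask) > 0, structure=_CONN26)
    if n == 0:
        return labels.astype(np.int32)
    if min_voxels > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_voxels) + 1
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
    return labels.astype(np.int32)


def detect_lesions(cube: np.ndarray, model, threshold: float = 0.5, min_voxels: int = 2,
                   spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    """Run a detector over a normalized cube and label candidate lesions.

    ``model`` is any object with ``predict_proba(cube) -> probability map``
    of the same shape (a fitted :class:`MetastasisDetector3D`, or an oracle
    that replays ground-truth probabilities).
    """
    cube = np.asarray(cube)
    prob = np.asarray(model.predict_proba(cube))
    if prob.shape != cube.shape:
        raise ValueError(f"model output shape {prob.shape} != input {cube.shape}")
    return LabelMap(label_components(prob >= threshold, min_voxels), spacing)


def extract_bounding_boxes(labels: LabelMap | np.ndarray, margin: int = 0) -> list[BoundingBox]:
    """Tight box per label id (ascending), expanded by ``margin`` and clamped."""
    arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    boxes = []
    slices = ndimage.find_objects(arr)
    for sl in slices:
        if sl is None:
            continue
        box = BoundingBox(tuple(s.start for s in sl), tuple(s.stop for s in sl))
        boxes.append(box.expand(margin, arr.shape) if margin else box)
    return boxes
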
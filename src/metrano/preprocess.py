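"""Intensity normalization, brain masking/cropping, cube resampling.

Scanner intensities on T1-weighted MRI are arbitrary, so volumes are
rescaled to [0, 1] anchored on a gray-matter reference intensity: the
mapping is ``v -> clip(v / (2 * gm_reference), 0, 1)``, which places the
gray-matter level at 0.5 and saturates strongly-enhancing tissue at 1.
Background voxels (outside the brain mask) are forced to exactly 0.

Detection runs on a fixed isotropic cube (default 192³): the brain-cropped
volume is scaled by one global factor so the longest axis fills the cube,
aspect ratio preserved, and the rest is zero padding. Every geometric step
records enough bookkeeping for an exact inverse mapping back to the native
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volio import BoundingBox, LabelMap, Volume3D

__all__ = [
    "NormalizedVolume",
    "ResampleRecord",
    "normalize_intensity",
    "estimate_background_mask",
    "extract_brain_mask",
    "crop_to_brain",
    "resample_isotropic_cube",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NormalizedVolume:
    """A Volume3D with intensities in [0, 1], plus its normalization anchor."""

    volume: Volume3D
    gm_reference: float
    brain_mask: np.ndarray  # True inside the brain (non-background)

    def __post_init__(self) -> None:
        if self.brain_mask.shape != self.volume.shape:
            raise ValueError("brain mask shape mismatch")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def spacing(self):
        return self.volume.spacing


def estimate_background_mask(vol: Volume3D, fraction: float = 0.02) -> np.ndarray:
    """Mask-free background proxy: voxels below ``fraction`` of the 99th
    intensity percentile are treated as background (air)."""
    thr = fraction * np.percentile(vol.data, 99)
    return vol.data <= thr


def normalize_intensity(
    vol: Volume3D,
    gm_reference: float | str | None = "auto",
    background_mask: np.ndarray | None = None,
) -> NormalizedVolume:
    """Rescale intensities to [0, 1] anchored at a gray-matter reference.

    ``gm_reference="auto"`` uses the median intensity of the non-background
    voxels (an automated stand-in for a manually picked gray-matter point);
    an explicit positive float overrides it. ``v = gm_reference`` maps to
    0.5; values at or above twice the reference saturate at 1.
    """
    if background_mask is None:
        background_mask = estimate_background_mask(vol)
    if background_mask.shape != vol.shape:
        raise ValueError(f"background mask shape {background_mask.shape} != volume shape {vol.shape}")
    brain = ~background_mask
    if gm_reference in ("auto", None):
        if not brain.any():
            raise ValueError("cannot auto-estimate gray-matter reference: no foreground voxels")
        gm_reference = float(np.median(vol.data[brain]))
    gm_reference = float(gm_reference)
    if gm_reference <= 0:
        raise ValueError(f"gm_reference must be positive, got {gm_reference}")
    out = np.clip(vol.data / (2.0 * gm_reference), 0.0, 1.0)
    out[background_mask] = 0.0
    return NormalizedVolume(Volume3D(out, vol.spacing, vol.origin), gm_reference, brain)


def extract_brain_mask(vol: Volume3D, segmenter=None) -> LabelMap:
    """Binary brain mask: largest 26-connected foreground component with
    axial slice-wise hole filling.

    ``segmenter`` may be any object with a ``predict(data) -> probability``
    method (e.g. a trained segmenter); by default an Otsu threshold is used,
    which is exact on zero-background scans.
    """
    if segmenter is not None:
        prob = segmenter.predict(vol.data)
        fg = np.asarray(prob) >= 0.5
    else:
        if not (vol.data > 0).any():
            raise ValueError("no brain found: volume is entirely non-positive")
        thr = threshold_otsu(vol.data)
        fg = vol.data > thr
    if not fg.any():
        raise ValueError("no brain found: foreground empty")
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_closing(fg, structure=ndimage.generate_binary_structure(3, 2))
    for z in range(fg.shape[2]):
        fg[:, :, z] = ndimage.binary_fill_holes(fg[:, :, z])
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:  # closing cannot split, but guard anyway
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return LabelMap(fg.astype(np.int32), vol.spacing, vol.origin)


def crop_to_brain(
    vol: Volume3D, mask: LabelMap | np.ndarray, margin_voxels: int = 2
) -> tuple[Volume3D, BoundingBox]:
    """Restrict a volume to the (margin-padded) tight box of the brain mask.

    The returned box is in native voxel indices, so results computed on the
    crop map back exactly; the crop keeps a world-consistent origin.
    """
    m = mask.mask() if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    if not m.any():
        raise ValueError("empty brain mask")
    box = BoundingBox.of_mask(m).expand(margin_voxels, vol.shape)
    sub = vol.data[box.slices()]
    origin = tuple(o + lo * s for o, lo, s in zip(vol.origin, box.lo, vol.spacing))
    return Volume3D(sub, vol.spacing, origin), box


@dataclass(frozen=True)
class ResampleRecord:
    """Bookkeeping for the aspect-preserving resample into an isotropic cube.

    One global target spacing ``t = max(physical extent)/size`` applies to
    all axes; the content spans ``content_shape`` voxels and is centered by
    ``offset`` voxels of zero padding. The forward/inverse index mappings
    are exact closed forms.
    """

    native_shape: tuple[int, int, int]
    native_spacing: tuple[float, float, float]
    size: int
    target_spacing: float
    content_shape: tuple[int, int, int]
    offset: tuple[int, int, int]

    def cube_to_native(self, cube_idx: np.ndarray) -> np.ndarray:
        """Continuous native voxel index of (possibly fractional) cube indices."""
        u = np.asarray(cube_idx, dtype=float)
        p = np.asarray(self.native_spacing)
        o = np.asarray(self.offset)
        return (u - o + 0.5) * self.target_spacing / p - 0.5

    def native_to_cube(self, native_idx: np.ndarray) -> np.ndarray:
        i = np.asarray(native_idx, dtype=float)
        p = np.asarray(self.native_spacing)
        o = np.asarray(self.offset)
        return (i + 0.5) * p / self.target_spacing - 0.5 + o

    def _cube_sample_coords(self) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(self.size)] * 3, indexing="ij")
        u = np.stack(grids, axis=-1)
        return np.moveaxis(self.cube_to_native(u), -1, 0)

    def resample_intensity(self, data: np.ndarray) -> np.ndarray:
        """Trilinear resample of native data into the zero-padded cube."""
        coords = self._cube_sample_coords()
        return ndimage.map_coordinates(data.astype(np.float32), coords, order=1, mode="constant", cval=0.0)

    def resample_labels(self, labels: np.ndarray) -> np.ndarray:
        """Nearest-neighbor resample of native labels into the cube."""
        coords = self._cube_sample_coords()
        return ndimage.map_coordinates(labels, coords, order=0, mode="constant", cval=0)

    def labels_to_native(self, cube_labels: np.ndarray) -> np.ndarray:
        """Nearest-neighbor inverse: pull cube labels back onto the native grid."""
        grids = np.meshgrid(*[np.arange(n) for n in self.native_shape], indexing="ij")
        i = np.stack(grids, axis=-1)
        u = np.rint(self.native_to_cube(i)).astype(int)
        inside = np.all((u >= 0) & (u < self.size), axis=-1)
        out = np.zeros(self.native_shape, dtype=cube_labels.dtype)
        out[inside] = cube_labels[u[inside, 0], u[inside, 1], u[inside, 2]]
        return out

    def box_to_native(self, box: BoundingBox) -> BoundingBox:
        """Map a cube-space box to the smallest covering native-grid box."""
        lo = self.cube_to_native(np.asarray(box.lo, dtype=float) - 0.5)
        hi = self.cube_to_native(np.asarray(box.hi, dtype=float) - 0.5)
        lo_i = np.maximum(0, np.floor(lo + 0.5)).astype(int)
        hi_i = np.minimum(self.native_shape, np.ceil(hi + 0.5)).astype(int)
        hi_i = np.maximum(hi_i, lo_i + 1)
        return BoundingBox(tuple(lo_i), tuple(np.minimum(hi_i, self.native_shape)))


def resample_isotropic_cube(vol: Volume3D, size: int = 192) -> tuple[Volume3D, ResampleRecord]:
    """Resample into a ``size``³ isotropic cube, aspect ratio preserved.

    The longest physical axis maps to ``size`` voxels; shorter axes are
    centered with zero padding.
    """
    if size < 8:
        raise ValueError(f"cube size must be >= 8, got {size}")
    extent = np.asarray(vol.shape) * np.asarray(vol.spacing)
    t = float(extent.max() / size)
    content = np.minimum(np.rint(extent / t).astype(int), size)
    offset = tuple(int(v) for v in (size - content) // 2)
    record = ResampleRecord(vol.shape, vol.spacing, size, t, tuple(int(c) for c in content), offset)
    cube = record.resample_intensity(vol.data)
    return Volume3D(cube, (t, t, t)), record
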
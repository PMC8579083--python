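"""Core volumetric data model and NIfTI-1 I/O.

Conventions used throughout the package:

* axis order is ``(x, y, z)`` with ``z`` the axial (slice) direction, so an
  axial plane is a fixed-``z`` slab ``data[:, :, z]``;
* voxel indices are 0-based and voxel-centered: the world coordinate of
  voxel ``i`` is ``origin + i * spacing``;
* boxes are half-open ``[min, max)`` in voxel indices.

NIfTI-1 (``.nii``/``.nii.gz``) is the sole on-disk image format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "LabelMap", "BoundingBox", "read_volume", "write_volume"]


@dataclass
class Volume3D:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units. Must be finite.
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm/voxel, all positive.
    origin : tuple of float
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be three positive numbers, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of 0-based voxel indices, voxel-centered."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_geometry(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, self.origin)


@dataclass
class LabelMap:
    """Non-negative integer lesion labels on the grid of a companion volume.

    0 is background; lesions carry contiguous positive integer labels.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label map must contain integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def ids(self) -> list[int]:
        u = np.unique(self.labels)
        return [int(v) for v in u if v > 0]

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.labels > 0
        return self.labels == label

    def as_volume(self) -> Volume3D:
        return Volume3D(self.labels.astype(np.int32), self.spacing, self.origin)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel-index box ``[lo, hi)``; ``lo < hi`` on every axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if any(a >= b for a, b in zip(lo, hi)):
            raise ValueError(f"degenerate box: lo={lo} hi={hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.lo, self.hi))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))  # type: ignore[return-value]

    def expand(self, margin: int | tuple[int, int, int], grid_shape: tuple[int, int, int]) -> "BoundingBox":
        """Grow by ``margin`` voxels per face, clamped to ``[0, grid_shape)``."""
        m = (margin, margin, margin) if np.isscalar(margin) else tuple(margin)  # type: ignore[assignment]
        lo = tuple(max(0, a - int(mi)) for a, mi in zip(self.lo, m))
        hi = tuple(min(n, b + int(mi)) for b, mi, n in zip(self.hi, m, grid_shape))
        return BoundingBox(lo, hi)

    def contains_box(self, other: "BoundingBox") -> bool:
        return all(a <= c and d <= b for a, b, c, d in zip(self.lo, self.hi, other.lo, other.hi))

    @staticmethod
    def of_mask(mask: np.ndarray) -> "BoundingBox":
        """Tight half-open box of the True voxels of ``mask``."""
        if not mask.any():
            raise ValueError("cannot take bounding box of an empty mask")
        lo, hi = [], []
        for ax in range(3):
            proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
            nz = np.nonzero(proj)[0]
            lo.append(int(nz[0]))
            hi.append(int(nz[-1]) + 1)
        return BoundingBox(tuple(lo), tuple(hi))


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 file as a :class:`Volume3D`.

    The image is reoriented to the package's closest-to-RAS ``(x, y, z)``
    axis convention; spacing and origin come from the header affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image in {path.name}")
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite voxels in {path.name}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return Volume3D(np.ascontiguousarray(data), tuple(float(z) for z in zooms), tuple(float(o) for o in origin))


def write_volume(vol: Volume3D | LabelMap, path: str | Path) -> Path:
    """Write a volume or label map to NIfTI-1; returns the path written.

    Integer data round-trips bit-exactly; floats are stored as float32
    unless already float64.
    """
    path = Path(path)
    if isinstance(vol, LabelMap):
        data, spacing, origin = vol.labels.astype(np.int32), vol.spacing, vol.origin
    else:
        data, spacing, origin = vol.data, vol.spacing, vol.origin
        if data.dtype not in (np.float32, np.float64) and not np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from_geometry(spacing, origin))
    img.header.set_zooms(spacing)
    try:
        nib.save(img, str(path))
    except OSError as err:
        raise OSError(f"cannot write volume to {path}: {err}") from err
    return path
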
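"""7-parameter similarity transform between serial scans.

A similarity transform is a rigid-body motion (3 Euler rotations + 3
translations) plus one isotropic scale factor, the model used to align a
patient's baseline and follow-up head scans where anatomy is preserved but
positioning and minor calibration differ.

Convention: world point ``x`` maps to ``y = c + s * R (x - c) + t`` where
``c`` is the rotation center (mm), ``R`` the rotation from extrinsic
(fixed-frame) XYZ Euler angles, ``s`` the isotropic scale and ``t`` the
translation (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["SimilarityTransform"]


@dataclass(frozen=True)
class SimilarityTransform:
    """Rigid rotation + translation with one isotropic scale.

    Parameters
    ----------
    angles_deg : tuple of float
        Euler angles about the fixed X, Y, Z world axes, in degrees.
    translation_mm : tuple of float
        Translation ``(tx, ty, tz)`` in mm.
    scale : float
        Isotropic scale factor, > 0.
    center_mm : tuple of float
        Center of rotation/scaling in world mm.
    """

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
        object.__setattr__(self, "translation_mm", tuple(float(t) for t in self.translation_mm))
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))
        object.__setattr__(self, "scale", float(self.scale))
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.angles_deg, degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the mapping (center folded in)."""
        R = self.scale * self.rotation_matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points, shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        R = self.rotation_matrix
        return c + self.scale * (p - c) @ R.T + t

    def inverse(self) -> "SimilarityTransform":
        """Closed-form inverse, expressed about the same center."""
        R = self.rotation_matrix
        Rinv = R.T
        angles = Rotation.from_matrix(Rinv).as_euler("xyz", degrees=True)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        # Solve y = c + sR(x - c) + t for x: x = c + (1/s) R^T (y - c - t)
        # In the canonical form about c: x = c + s' R'(y - c) + t' with
        # s' = 1/s, R' = R^T, t' = -(1/s) R^T t
        t_inv = -(Rinv @ t) / self.scale
        return SimilarityTransform(tuple(angles), tuple(t_inv), 1.0 / self.scale, self.center_mm)

    def compose(self, first: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self ∘ first`` (apply ``first``, then ``self``)."""
        M = self.matrix @ first.matrix
        s = float(np.linalg.det(M[:3, :3]) ** (1.0 / 3.0))
        R = M[:3, :3] / s
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        c = np.asarray(self.center_mm)
        # canonical form about self's center: t = M c + m - c where m is M's offset
        t = M[:3, :3] @ c + M[:3, 3] - c
        return SimilarityTransform(tuple(angles), tuple(t), s, self.center_mm)

    def is_identity(self, atol_deg: float = 1e-9, atol_mm: float = 1e-9, atol_scale: float = 1e-9) -> bool:
        return (
            max(abs(a) for a in self.angles_deg) <= atol_deg
            and max(abs(t) for t in self.translation_mm) <= atol_mm
            and abs(self.scale - 1.0) <= atol_scale
        )

    def to_dict(self) -> dict:
        return {
            "angles_deg": list(self.angles_deg),
            "translation_mm": list(self.translation_mm),
            "scale": self.scale,
            "center_mm": list(self.center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            tuple(d["angles_deg"]), tuple(d["translation_mm"]), d["scale"], tuple(d.get("center_mm", (0, 0, 0)))
        )
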
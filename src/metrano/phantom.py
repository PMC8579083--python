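"""Seeded longitudinal brain phantoms with exact lesion ground truth.

The generator produces contrast-enhanced-T1-like volumes: a brain-shaped
foreground (smooth ellipsoid with mild seeded intensity gradients around a
gray-matter reference level) on an exactly-zero background, carrying
quasi-spherical hyperintense lesions of controlled diameter, plus additive
Gaussian noise. Follow-up scans are related to baseline by a known
similarity transform (rotation + translation + isotropic scale) with
per-lesion growth/shrinkage/appearance/disappearance, and are rendered
analytically — every anatomy implicit function is evaluated at the
inverse-transformed coordinates — so the recorded ground truth (masks,
centers, diameters, transform) is exact rather than interpolated.

All randomness flows from explicit integer seeds; the same seed and
configuration reproduce volumes bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .transform import SimilarityTransform
from .volio import LabelMap, Volume3D, write_volume

__all__ = [
    "PhantomConfig",
    "LesionSpec",
    "BrainSpec",
    "FollowupChanges",
    "PhantomTruth",
    "generate_phantom",
    "generate_followup",
    "write_study",
]

_NOISE_STREAM = 0x5EED  # sub-seed tag separating noise draws from placement draws


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    Defaults mirror a 1 mm isotropic post-contrast 3D T1 protocol with a
    handful of enhancing metastases per scan (median clinical nodule sizes
    are ~6–7 mm with interquartile range roughly 5–10 mm).
    """

    shape: tuple[int, int, int] = (160, 192, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: tuple[int, int] = (2, 5)  # inclusive range
    diameter_range_mm: tuple[float, float] = (3.0, 14.0)
    contrast_range: tuple[float, float] = (1.5, 3.0)
    gm_intensity: float = 100.0
    noise_sigma: float = 3.0
    # distinctly triaxial, like a head (wider laterally than tall): all three
    # axes differ so every rotation component is observable to registration
    brain_radii_frac: tuple[float, float, float] = (0.34, 0.40, 0.28)
    gradient_amplitude: float = 0.08
    lesion_margin_mm: float = 2.0
    max_placement_tries: int = 2000

    @classmethod
    def tiny(cls, **overrides) -> "PhantomConfig":
        """64³ profile for fast CPU tests: same physics, smaller grid and
        proportionally fewer/smaller lesions so placement stays feasible."""
        cfg = cls(shape=(64, 64, 64), n_lesions=(2, 3), diameter_range_mm=(3.0, 10.0))
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class LesionSpec:
    """One quasi-spherical enhancing lesion, in baseline world coordinates."""

    id: int
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    contrast: float  # multiple of the gray-matter reference intensity

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(c) for c in self.center_mm)
        self.radii_mm = tuple(float(r) for r in self.radii_mm)
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"lesion {self.id}: radii must be positive, got {self.radii_mm}")

    @property
    def diameter_mm(self) -> float:
        """Longest axial-plane diameter: twice the max in-plane radius."""
        return 2.0 * max(self.radii_mm[0], self.radii_mm[1])

    @property
    def volume_mm3(self) -> float:
        rx, ry, rz = self.radii_mm
        return 4.0 / 3.0 * np.pi * rx * ry * rz


@dataclass
class BrainSpec:
    """Smooth ellipsoidal brain foreground with a seeded intensity gradient."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    grad_amps: tuple[float, ...]
    grad_freqs: tuple[tuple[float, float, float], ...]  # rad/mm wave vectors
    grad_phases: tuple[float, ...]

    def ellipsoid_norm(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center_mm)) / np.asarray(self.radii_mm)
        return np.einsum("...i,...i->...", d, d)

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        g = np.zeros(pts.shape[:-1])
        for a, w, ph in zip(self.grad_amps, self.grad_freqs, self.grad_phases):
            g += a * np.sin(pts @ np.asarray(w) + ph)
        return g


@dataclass
class FollowupChanges:
    """Per-lesion evolution between baseline and follow-up.

    ``factors`` scales each persisting lesion's radii; ids in ``removed``
    disappear; ``added`` lesions (given in baseline anatomical coordinates)
    appear only on follow-up.
    """

    factors: dict[int, float] = field(default_factory=dict)
    removed: tuple[int, ...] = ()
    added: tuple[LesionSpec, ...] = ()


@dataclass
class PhantomTruth:
    """Exact generating parameters of one phantom scan.

    Anatomy (brain, lesions) is stored in the baseline frame; for a
    follow-up scan ``transform`` maps baseline world coordinates to this
    scan's world coordinates and image-frame lesion geometry is derived
    through it.
    """

    seed: int
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    gm_intensity: float
    noise_sigma: float
    brain: BrainSpec
    lesions: list[LesionSpec]
    transform: SimilarityTransform | None = None
    changes: FollowupChanges | None = None

    # -- image-frame geometry -------------------------------------------------
    def lesion_center_world(self, lesion: LesionSpec) -> np.ndarray:
        c = np.asarray(lesion.center_mm, dtype=float)
        return c if self.transform is None else self.transform.apply(c)

    def lesion_radii_world(self, lesion: LesionSpec) -> np.ndarray:
        s = 1.0 if self.transform is None else self.transform.scale
        return s * np.asarray(lesion.radii_mm)

    def lesion_diameter_world(self, lesion: LesionSpec) -> float:
        r = self.lesion_radii_world(lesion)
        return float(2.0 * max(r[0], r[1]))

    def diameters_by_id(self) -> dict[int, float]:
        return {l.id: self.lesion_diameter_world(l) for l in self.lesions}

    def volumes_by_id(self) -> dict[int, float]:
        s = 1.0 if self.transform is None else self.transform.scale
        return {l.id: float(l.volume_mm3 * s**3) for l in self.lesions}

    def centers_by_id(self) -> dict[int, np.ndarray]:
        return {l.id: self.lesion_center_world(l) for l in self.lesions}

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "gm_intensity": self.gm_intensity,
            "noise_sigma": self.noise_sigma,
            "brain": {
                "center_mm": list(self.brain.center_mm),
                "radii_mm": list(self.brain.radii_mm),
                "grad_amps": list(self.brain.grad_amps),
                "grad_freqs": [list(f) for f in self.brain.grad_freqs],
                "grad_phases": list(self.brain.grad_phases),
            },
            "lesions": [
                {"id": l.id, "center_mm": list(l.center_mm), "radii_mm": list(l.radii_mm), "contrast": l.contrast}
                for l in self.lesions
            ],
            "transform": None if self.transform is None else self.transform.to_dict(),
            "changes": None,
        }
        if self.changes is not None:
            d["changes"] = {
                "factors": {str(k): v for k, v in self.changes.factors.items()},
                "removed": list(self.changes.removed),
                "added": [
                    {"id": l.id, "center_mm": list(l.center_mm), "radii_mm": list(l.radii_mm), "contrast": l.contrast}
                    for l in self.changes.added
                ],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        brain = BrainSpec(
            tuple(d["brain"]["center_mm"]),
            tuple(d["brain"]["radii_mm"]),
            tuple(d["brain"]["grad_amps"]),
            tuple(tuple(f) for f in d["brain"]["grad_freqs"]),
            tuple(d["brain"]["grad_phases"]),
        )
        lesions = [
            LesionSpec(l["id"], tuple(l["center_mm"]), tuple(l["radii_mm"]), l["contrast"]) for l in d["lesions"]
        ]
        transform = None if d.get("transform") is None else SimilarityTransform.from_dict(d["transform"])
        changes = None
        if d.get("changes") is not None:
            ch = d["changes"]
            changes = FollowupChanges(
                {int(k): v for k, v in ch["factors"].items()},
                tuple(ch["removed"]),
                tuple(
                    LesionSpec(l["id"], tuple(l["center_mm"]), tuple(l["radii_mm"]), l["contrast"])
                    for l in ch["added"]
                ),
            )
        return cls(
            d["seed"], tuple(d["shape"]), tuple(d["spacing"]), d["gm_intensity"], d["noise_sigma"],
            brain, lesions, transform, changes,
        )


# -----------------------------------------------------------------------------
# rendering
# -----------------------------------------------------------------------------

def _grid_world(shape, spacing) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _render(truth: PhantomTruth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the phantom's implicit anatomy on its grid.

    Returns (intensity without noise, label map, brain mask). For a
    follow-up scan the grid coordinates are pulled back to the baseline
    frame through the inverse transform before evaluation.
    """
    pts = _grid_world(truth.shape, truth.spacing)
    if truth.transform is not None:
        pts = truth.transform.inverse().apply(pts)
    brain = truth.brain
    inside = brain.ellipsoid_norm(pts) <= 1.0
    vol = np.zeros(truth.shape, dtype=np.float64)
    vol[inside] = truth.gm_intensity * (1.0 + brain.gradient(pts[inside]))
    labels = np.zeros(truth.shape, dtype=np.int32)
    for lesion in truth.lesions:
        d = (pts - np.asarray(lesion.center_mm)) / np.asarray(lesion.radii_mm)
        m = np.einsum("...i,...i->...", d, d) <= 1.0
        vol[m] = lesion.contrast * truth.gm_intensity
        labels[m] = lesion.id
    return vol, labels, inside


def _finalize(truth: PhantomTruth, seed: int) -> tuple[Volume3D, LabelMap, PhantomTruth]:
    vol, labels, inside = _render(truth)
    rng = np.random.default_rng([_NOISE_STREAM, seed])
    noise = rng.normal(0.0, truth.noise_sigma, size=truth.shape)
    vol[inside] = np.maximum(vol[inside] + noise[inside], 1e-3)  # keep foreground strictly positive
    return (
        Volume3D(vol, truth.spacing),
        LabelMap(labels, truth.spacing),
        truth,
    )


# -----------------------------------------------------------------------------
# generation
# -----------------------------------------------------------------------------

def _draw_brain(cfg: PhantomConfig, rng: np.random.Generator) -> BrainSpec:
    extent = np.asarray(cfg.shape) * np.asarray(cfg.spacing)
    center = tuple((extent - np.asarray(cfg.spacing)) / 2.0)
    radii = tuple(float(f * e) for f, e in zip(cfg.brain_radii_frac, extent))
    k = 3
    amps = rng.uniform(0.4, 1.0, size=k)
    amps = tuple(float(a) for a in cfg.gradient_amplitude * amps / amps.sum())
    freqs = []
    for _ in range(k):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wavelength = rng.uniform(40.0, 90.0)  # mm; low-frequency shading
        freqs.append(tuple(float(v) for v in 2 * np.pi / wavelength * direction))
    phases = tuple(float(p) for p in rng.uniform(0, 2 * np.pi, size=k))
    return BrainSpec(center, radii, amps, tuple(freqs), phases)


def _place_lesions(cfg: PhantomConfig, brain: BrainSpec, rng: np.random.Generator) -> list[LesionSpec]:
    n = int(rng.integers(cfg.n_lesions[0], cfg.n_lesions[1] + 1))
    bc = np.asarray(brain.center_mm)
    br = np.asarray(brain.radii_mm)
    # draw all sizes up front and place largest-first: big lesions are the
    # hardest to fit, so this keeps placement feasible on small grids
    draws = sorted(
        (float(rng.uniform(*cfg.diameter_range_mm)), float(rng.uniform(*cfg.contrast_range))) for _ in range(n)
    )[::-1]
    lesions: list[LesionSpec] = []
    for lesion_id, (diameter, contrast) in enumerate(draws, start=1):
        r = diameter / 2.0
        placed = False
        shrink = br - r - cfg.lesion_margin_mm
        for _ in range(cfg.max_placement_tries):
            if np.any(shrink <= 0):
                break
            cand = bc + rng.uniform(-1.0, 1.0, size=3) * shrink
            d = (cand - bc) / shrink
            if d @ d > 1.0:  # lesion entirely inside brain (shrunk ellipsoid)
                continue
            # separation leaves room for 1.4x growth without merging components
            ok = all(
                np.linalg.norm(cand - np.asarray(other.center_mm)) >= 1.4 * (r + max(other.radii_mm)) + 1.0
                for other in lesions
            )
            if ok:
                lesions.append(LesionSpec(lesion_id, tuple(float(c) for c in cand), (r, r, r), contrast))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {lesion_id} (diameter {diameter:.1f} mm) inside the brain "
                f"after {cfg.max_placement_tries} tries"
            )
    return lesions


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> tuple[Volume3D, LabelMap, PhantomTruth]:
    """Generate one baseline phantom scan with exact ground truth.

    Deterministic: the same ``config`` and ``seed`` reproduce the volume
    bit-for-bit.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    brain = _draw_brain(cfg, rng)
    lesions = _place_lesions(cfg, brain, rng)
    truth = PhantomTruth(
        seed, tuple(cfg.shape), tuple(cfg.spacing), cfg.gm_intensity, cfg.noise_sigma, brain, lesions
    )
    return _finalize(truth, seed)


def generate_followup(
    baseline: PhantomTruth,
    transform: SimilarityTransform,
    changes: FollowupChanges | None = None,
    seed: int | None = None,
) -> tuple[Volume3D, LabelMap, PhantomTruth]:
    """Render the follow-up scan of a baseline phantom.

    The anatomy is the baseline anatomy moved by ``transform`` (the scan
    grid is resampled through its inverse) with per-lesion changes applied.
    ``seed`` controls only the noise draw; reusing the baseline seed with an
    identity transform and no changes reproduces the baseline voxelwise.
    """
    changes = changes or FollowupChanges()
    seed = baseline.seed if seed is None else seed
    _check_brain_inside(baseline, transform)
    lesions: list[LesionSpec] = []
    for l in baseline.lesions:
        if l.id in changes.removed:
            continue
        f = changes.factors.get(l.id, 1.0)
        if f <= 0:
            raise ValueError(f"change factor for lesion {l.id} must be positive, got {f}")
        lesions.append(LesionSpec(l.id, l.center_mm, tuple(f * r for r in l.radii_mm), l.contrast))
    next_id = max((l.id for l in baseline.lesions), default=0) + 1
    added = []
    for spec in changes.added:
        new_id = spec.id if spec.id and spec.id >= next_id else next_id
        added.append(LesionSpec(new_id, spec.center_mm, spec.radii_mm, spec.contrast))
        next_id = new_id + 1
    changes = FollowupChanges(dict(changes.factors), tuple(changes.removed), tuple(added))
    truth = PhantomTruth(
        seed, baseline.shape, baseline.spacing, baseline.gm_intensity, baseline.noise_sigma,
        baseline.brain, lesions + added, transform, changes,
    )
    return _finalize(truth, seed)


def _check_brain_inside(baseline: PhantomTruth, transform: SimilarityTransform) -> None:
    """Reject transforms that push the brain ellipsoid off the scan grid."""
    bc = np.asarray(baseline.brain.center_mm)
    br = np.asarray(baseline.brain.radii_mm)
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    phi = np.linspace(0, np.pi, 13)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    surface = bc + np.stack(
        [br[0] * np.sin(pp) * np.cos(tt), br[1] * np.sin(pp) * np.sin(tt), br[2] * np.cos(pp)], axis=-1
    ).reshape(-1, 3)
    mapped = transform.apply(surface)
    extent = (np.asarray(baseline.shape) - 1) * np.asarray(baseline.spacing)
    if np.any(mapped < -1e-6) or np.any(mapped > extent + 1e-6):
        raise ValueError("transform moves the brain outside the scan grid")


# -----------------------------------------------------------------------------
# on-disk study layout
# -----------------------------------------------------------------------------

def write_study(
    studies: list[dict],
    out_dir: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a cohort of phantom scans plus ground truth and a manifest.

    ``studies`` is a list of dicts with keys ``subject`` (str) and
    ``baseline`` / optional ``followup``, each a ``(Volume3D, LabelMap,
    PhantomTruth)`` triple. Returns the manifest path.
    """
    if not studies:
        raise ValueError("empty study list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    entries = []
    for study in studies:
        subject = study["subject"]
        entry: dict = {"subject": subject}
        for role in ("baseline", "followup"):
            if role not in study or study[role] is None:
                continue
            vol, labels, truth = study[role]
            stem = f"{subject}_{role}"
            vol_p = write_volume(vol, out_dir / f"{stem}.nii.gz")
            lab_p = write_volume(labels, out_dir / f"{stem}_labels.nii.gz")
            truth_p = out_dir / f"{stem}_truth.json"
            truth_p.write_text(json.dumps(truth.to_dict(), indent=1))
            entry[role] = {"image": vol_p.name, "labels": lab_p.name, "truth": truth_p.name}
        entries.append(entry)
    manifest_path.write_text(json.dumps({"studies": entries}, indent=1))
    return manifest_path


def read_truth(path: str | Path) -> PhantomTruth:
    return PhantomTruth.from_dict(json.loads(Path(path).read_text()))
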
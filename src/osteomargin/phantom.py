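"""Digital skull + tumor phantom generation.

The physical study used artificial skulls with moldable tumor masses whose
x-ray attenuation exceeds the artificial bone.  The digital stand-in keeps
exactly the properties the downstream analysis consumes: a closed tumor
surface, attenuation contrast between tumor and bone, registration
fiducials drilled into the skull, and five named osteotomy corridors
(Pa, FMJ, LIOR, Zy, PMJ).

Geometry is deliberately simple — a hemispherical bone shell with tumors
built as unions of 1-3 overlapping ellipsoids — because nothing in the
margin analysis depends on anatomical realism.  Tumor sizes are invented
defaults (the physical models were never dimensioned); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .registration import RigidTransform

__all__ = [
    "Volume3D",
    "Ellipsoid",
    "TumorSpec",
    "PhantomSpec",
    "FiducialSet",
    "OsteotomySite",
    "SITE_IDS",
    "generate_phantom",
    "write_phantom",
    "read_phantom",
    "default_phantom_spec",
]

SITE_IDS = ("Pa", "FMJ", "LIOR", "Zy", "PMJ")

# Invented anatomical directions for the five osteotomy corridors, pointing
# outward from the tumor centroid roughly where each cut is made on a skull:
# palate inferior, fronto-maxillary superior-anterior, orbital rim
# supero-lateral, zygomatic arch lateral, pterygo-maxillary postero-lateral.
_SITE_DIRECTIONS = {
    "Pa": (0.0, 0.0, -1.0),
    "FMJ": (0.0, 0.7, 0.714142842854285),
    "LIOR": (0.6, 0.3, 0.741619848709566),
    "Zy": (1.0, 0.0, 0.0),
    "PMJ": (0.7, -0.6, 0.38729833462074165),
}


@dataclass
class Volume3D:
    """Regular 3D scalar grid with mm voxel spacing.

    ``values[i, j, k]`` is the sample at world position
    ``origin + (i, j, k) * spacing`` — axis 0 is x, axis 1 y, axis 2 z.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"values must be a 3D array, got shape {self.values.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world-mm points (no rounding)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (each 1D, per axis) of voxel centers."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax]) for ax in range(3)
        )


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.radii) <= 0:
            raise ValueError(f"ellipsoid radii must be positive, got {self.radii}")


@dataclass(frozen=True)
class TumorSpec:
    """One tumor mass: the union of 1-3 overlapping ellipsoids."""

    ellipsoids: tuple[Ellipsoid, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.ellipsoids) <= 3:
            raise ValueError("a tumor is a union of 1-3 ellipsoids")

    @property
    def center(self) -> np.ndarray:
        return np.mean([e.center for e in self.ellipsoids], axis=0)


@dataclass
class PhantomSpec:
    """Full parameterization of one digital phantom."""

    shape: tuple[int, int, int] = (256, 256, 256)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (-64.0, -64.0, -64.0)
    skull_center: tuple[float, float, float] = (0.0, 0.0, -20.0)
    skull_outer_radius: float = 55.0
    skull_thickness: float = 4.0
    tumors: tuple[TumorSpec, ...] = ()
    bone_level: float = 700.0
    tumor_level: float = 1200.0
    noise_sd: float = 30.0
    n_fiducials: int = 6
    fiducial_min_spacing: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tumors:
            self.tumors = (
                TumorSpec(
                    (
                        Ellipsoid((0.0, 8.0, 0.0), (14.0, 11.0, 12.0)),
                        Ellipsoid((6.0, -2.0, 4.0), (9.0, 12.0, 8.0)),
                    )
                ),
            )
        if not 1 <= len(self.tumors) <= 2:
            raise ValueError("phantoms carry 1-2 tumors")
        if self.tumor_level <= self.bone_level:
            raise ValueError(
                "tumor attenuation must exceed bone attenuation "
                f"(got tumor {self.tumor_level} <= bone {self.bone_level})"
            )
        if self.n_fiducials < 4:
            raise ValueError("at least 4 fiducials required for robust 3D registration")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class FiducialSet:
    """Paired fiducial positions in the image and tracker ("world") frames."""

    labels: list[str]
    positions_image: np.ndarray
    positions_world: np.ndarray

    def __post_init__(self) -> None:
        self.positions_image = np.asarray(self.positions_image, dtype=float)
        self.positions_world = np.asarray(self.positions_world, dtype=float)
        n = len(self.labels)
        if self.positions_image.shape != (n, 3) or self.positions_world.shape != (n, 3):
            raise ValueError("fiducial label/position lengths disagree")
        if n < 3:
            raise ValueError("at least 3 fiducials required")
        for pos in (self.positions_image, self.positions_world):
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            if dist.min() < 5.0:
                raise ValueError("fiducials closer than 5 mm — degenerate configuration")

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.positions_image, self.positions_world]),
            columns=["x_img", "y_img", "z_img", "x_world", "y_world", "z_world"],
        )
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(
            list(df["label"].astype(str)),
            df[["x_img", "y_img", "z_img"]].to_numpy(float),
            df[["x_world", "y_world", "z_world"]].to_numpy(float),
        )


@dataclass(frozen=True)
class OsteotomySite:
    """A named cut corridor: anchor point plus nominal plane axes."""

    site_id: str
    anchor: np.ndarray
    normal: np.ndarray
    longitudinal_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.site_id not in SITE_IDS:
            raise ValueError(f"unknown site id {self.site_id!r}; expected one of {SITE_IDS}")
        anchor = np.asarray(self.anchor, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        axis = np.asarray(self.longitudinal_axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(normal) - 1) > 1e-9 or abs(np.linalg.norm(axis) - 1) > 1e-9:
            raise ValueError("site normal and longitudinal axis must be unit vectors")
        if abs(normal @ axis) > 1e-9:
            raise ValueError("site longitudinal axis must be orthogonal to the normal")
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "normal", normal)
        object.__setattr__(self, "longitudinal_axis", axis)


def _perpendicular_unit(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to v."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(v, helper)
    return perp / np.linalg.norm(perp)


def _tumor_mask(spec: PhantomSpec, tumor: TumorSpec, grids) -> np.ndarray:
    gx, gy, gz = grids
    mask = np.zeros((gx.size, gy.size, gz.size), dtype=bool)
    for ell in tumor.ellipsoids:
        cx, cy, cz = ell.center
        rx, ry, rz = ell.radii
        term = (
            ((gx - cx) / rx)[:, None, None] ** 2
            + ((gy - cy) / ry)[None, :, None] ** 2
            + ((gz - cz) / rz)[None, None, :] ** 2
        )
        mask |= term <= 1.0
    return mask


def _place_fiducials(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample fiducial points on the outer skull shell with a spacing floor."""
    center = np.asarray(spec.skull_center, dtype=float)
    chosen: list[np.ndarray] = []
    for _ in range(10_000):
        # Uniform on the upper hemisphere of the outer shell.
        phi = rng.uniform(0, 2 * np.pi)
        cos_theta = rng.uniform(0.05, 1.0)
        sin_theta = np.sqrt(1 - cos_theta**2)
        direction = np.array(
            [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
        )
        candidate = center + spec.skull_outer_radius * direction
        if all(np.linalg.norm(candidate - p) >= spec.fiducial_min_spacing for p in chosen):
            chosen.append(candidate)
        if len(chosen) == spec.n_fiducials:
            return np.array(chosen)
    raise RuntimeError(
        "could not place fiducials with the requested spacing; "
        "reduce n_fiducials or fiducial_min_spacing"
    )


def _random_rigid(rng: np.random.Generator, source: str, target: str) -> RigidTransform:
    """Uniform random rotation (QR of a Gaussian matrix) + modest translation."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-100, 100, size=3)
    return RigidTransform(q, t, source, target)


def _make_sites(
    spec: PhantomSpec, tumor_center: np.ndarray
) -> list[OsteotomySite]:
    sites = []
    for sid in SITE_IDS:
        direction = np.asarray(_SITE_DIRECTIONS[sid], dtype=float)
        direction = direction / np.linalg.norm(direction)
        axis = _perpendicular_unit(direction)
        # Anchor sits out along the corridor direction; the exact tangent
        # offset to the tumor surface is resolved against the distance field
        # when a cut is planned.
        anchor = tumor_center + 30.0 * direction
        sites.append(OsteotomySite(sid, anchor, direction, axis))
    return sites


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Volume3D, Volume3D, FiducialSet, list[OsteotomySite], RigidTransform]:
    """Build the attenuation volume, tumor label volume, fiducials and sites.

    Deterministic given ``spec.seed``.  Returns, in order: the attenuation
    volume (background 0, bone and tumor at their configured levels, plus
    Gaussian noise), the integer label volume (tumor i -> label i+1), the
    fiducial set with exact world correspondences, the five osteotomy
    sites, and the ground-truth image->tracker transform used to produce
    the world fiducial positions.
    """
    rng = np.random.default_rng(spec.seed)
    if np.any(np.asarray(spec.spacing) <= 0):
        raise ValueError(f"voxel spacing must be positive, got {spec.spacing}")

    grids = tuple(
        np.asarray(spec.origin)[ax] + np.asarray(spec.spacing)[ax] * np.arange(spec.shape[ax])
        for ax in range(3)
    )
    gx, gy, gz = grids
    bounds_lo = np.array([gx[0], gy[0], gz[0]])
    bounds_hi = np.array([gx[-1], gy[-1], gz[-1]])

    label = np.zeros(spec.shape, dtype=np.int16)
    for idx, tumor in enumerate(spec.tumors, start=1):
        for ell in tumor.ellipsoids:
            lo = np.asarray(ell.center) - np.asarray(ell.radii)
            hi = np.asarray(ell.center) + np.asarray(ell.radii)
            if np.any(lo < bounds_lo) or np.any(hi > bounds_hi):
                raise ValueError(
                    f"tumor {idx} ellipsoid extends outside the volume bounds "
                    f"({lo} .. {hi} vs {bounds_lo} .. {bounds_hi})"
                )
        mask = _tumor_mask(spec, tumor, grids)
        label[mask] = idx

    center = np.asarray(spec.skull_center, dtype=float)
    radius2 = (
        ((gx - center[0]) ** 2)[:, None, None]
        + ((gy - center[1]) ** 2)[None, :, None]
        + ((gz - center[2]) ** 2)[None, None, :]
    )
    shell = (
        (radius2 <= spec.skull_outer_radius**2)
        & (radius2 >= (spec.skull_outer_radius - spec.skull_thickness) ** 2)
        & (gz[None, None, :] >= center[2])
    )

    values = np.zeros(spec.shape, dtype=np.float64)
    values[shell] = spec.bone_level
    values[label > 0] = spec.tumor_level
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = Volume3D(values, spec.spacing, spec.origin)
    label_volume = Volume3D(label, spec.spacing, spec.origin)

    fid_image = _place_fiducials(spec, rng)
    image_to_world = _random_rigid(rng, "image", "tracker")
    fiducials = FiducialSet(
        [f"F{i + 1}" for i in range(spec.n_fiducials)],
        fid_image,
        image_to_world.apply(fid_image),
    )
    sites = _make_sites(spec, spec.tumors[0].center)
    return volume, label_volume, fiducials, sites, image_to_world


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The study's default phantom at CBCT-like 0.5 mm resolution."""
    return PhantomSpec(seed=seed, **overrides)


def write_phantom(volume: Volume3D, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if not (suffixes.endswith(".nii") or suffixes.endswith(".nii.gz") or suffixes.endswith(".mha")):
        raise ValueError(f"unsupported volume format {path.name!r}; use .nii, .nii.gz or .mha")
    # SimpleITK array layout is (z, y, x); ours is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_phantom(path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffixes = "".join(path.suffixes)
    if not (suffixes.endswith(".nii") or suffixes.endswith(".nii.gz") or suffixes.endswith(".mha")):
        raise ValueError(f"unsupported volume format {path.name!r}; use .nii, .nii.gz or .mha")
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing(), dtype=float)
    origin = np.array(img.GetOrigin(), dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"corrupt header: non-positive voxel spacing {spacing}")
    return Volume3D(values, spacing, origin)
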
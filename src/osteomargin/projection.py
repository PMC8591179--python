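"""Tracked-projector geometry for projected augmented reality.

The AR system renders the registered tumor surface with a portable
projector whose case carries an optical reference, so both the projector
and the skull are tracked and the projected outline stays registered when
either is repositioned.  This module models that geometry: a pinhole
projector (known intrinsics, tracked pose), pose estimation from paired
2D-3D landmarks with the study's <1 mm alignment gate, and ray casting of
projected pixels onto the skull surface ("landing points").

Registration preservation under repositioning is a statement about the
tracked transform chain: points of the projected outline that lie on the
skull surface land at the same skull-frame locations after the skull or
the projector is moved and the chain is updated.  For points *inside* the
skull (the tumor body) the landing point necessarily shifts with projector
pose — the parallax effect — which :func:`landing_points` makes directly
measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .meshdist import ray_mesh_first_hit
from .registration import RigidTransform, compose

__all__ = [
    "ProjectorIntrinsics",
    "ProjectorModel",
    "LandingPointSet",
    "project_points",
    "register_projector",
    "landing_points",
]


@dataclass(frozen=True)
class ProjectorIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 1920
    height: int = 1080

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx <= self.width and 0 <= self.cy <= self.height):
            raise ValueError("principal point must lie inside the image")

    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class ProjectorModel:
    """Intrinsics plus the world -> projector rigid pose."""

    intrinsics: ProjectorIntrinsics
    pose: RigidTransform  # maps world-frame points into the projector frame

    def to_json(self) -> str:
        return json.dumps(
            {
                "intrinsics": {
                    "fx": self.intrinsics.fx,
                    "fy": self.intrinsics.fy,
                    "cx": self.intrinsics.cx,
                    "cy": self.intrinsics.cy,
                    "width": self.intrinsics.width,
                    "height": self.intrinsics.height,
                },
                "pose": json.loads(self.pose.to_json()),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProjectorModel":
        obj = json.loads(text)
        return cls(
            ProjectorIntrinsics(**obj["intrinsics"]),
            RigidTransform.from_json(json.dumps(obj["pose"])),
        )


@dataclass(frozen=True)
class LandingPointSet:
    """Where projected vertices land on the skull surface.

    ``pixels`` are the projector-image coordinates of each vertex;
    ``points_skull`` the 3D ray-surface intersections in the skull
    reference frame; ``hit`` flags rays that actually met the surface.
    """

    pixels: np.ndarray  # (N, 2)
    points_skull: np.ndarray  # (N, 3); NaN where hit is False
    hit: np.ndarray  # (N,) bool


def project_points(
    model: ProjectorModel, points_world: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pinhole projection of world points; returns (pixels, valid flags).

    A point is flagged invalid (pixel = NaN) when its depth in the
    projector frame is non-positive or it falls outside the image frame;
    nothing is silently dropped.
    """
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    cam = model.pose.apply(pts)
    z = cam[:, 2]
    valid = z > 1e-9
    pix = np.full((len(pts), 2), np.nan)
    intr = model.intrinsics
    with np.errstate(divide="ignore", invalid="ignore"):
        pix[valid, 0] = intr.fx * cam[valid, 0] / z[valid] + intr.cx
        pix[valid, 1] = intr.fy * cam[valid, 1] / z[valid] + intr.cy
    in_frame = (
        valid
        & (pix[:, 0] >= 0)
        & (pix[:, 0] <= intr.width)
        & (pix[:, 1] >= 0)
        & (pix[:, 1] <= intr.height)
    )
    return pix, in_frame


# 24 proper rotations of the cube group, used as deterministic pose seeds.
def _rotation_seeds() -> list[np.ndarray]:
    seeds = []
    axes = [
        np.eye(3),
        Rotation.from_euler("x", 90, degrees=True).as_matrix(),
        Rotation.from_euler("x", 180, degrees=True).as_matrix(),
        Rotation.from_euler("x", 270, degrees=True).as_matrix(),
        Rotation.from_euler("y", 90, degrees=True).as_matrix(),
        Rotation.from_euler("y", 270, degrees=True).as_matrix(),
    ]
    spins = [Rotation.from_euler("z", a, degrees=True).as_matrix() for a in (0, 90, 180, 270)]
    for base in axes:
        for spin in spins:
            seeds.append(base @ spin)
    return seeds


_ROTATION_SEEDS = _rotation_seeds()


def _reprojection_residuals(
    params: np.ndarray,
    pixels: np.ndarray,
    points: np.ndarray,
    intr: ProjectorIntrinsics,
) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    cam = points @ rot.T + params[3:]
    z = np.maximum(cam[:, 2], 1e-6)
    u = intr.fx * cam[:, 0] / z + intr.cx
    v = intr.fy * cam[:, 1] / z + intr.cy
    return np.concatenate([u - pixels[:, 0], v - pixels[:, 1]])


def _ray_point_rms(
    pose: RigidTransform,
    pixels: np.ndarray,
    points_world: np.ndarray,
    intr: ProjectorIntrinsics,
) -> float:
    """RMS 3D distance between each landmark and its back-projected ray."""
    inv = pose.inverse()
    center = inv.translation
    dirs_cam = np.column_stack(
        [
            (pixels[:, 0] - intr.cx) / intr.fx,
            (pixels[:, 1] - intr.cy) / intr.fy,
            np.ones(len(pixels)),
        ]
    )
    dirs = dirs_cam @ inv.rotation.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    rel = points_world - center
    along = np.sum(rel * dirs, axis=1, keepdims=True)
    perp = rel - along * dirs
    return float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))


def register_projector(
    image_landmarks: np.ndarray,
    surface_landmarks: np.ndarray,
    intrinsics: ProjectorIntrinsics,
    gate_mm: float = 1.0,
) -> tuple[RigidTransform, float, float, bool]:
    """Estimate the projector pose from paired pixel / 3D landmarks.

    Minimizes reprojection error over the 6-DOF pose, started from a
    deterministic bank of 24 orientation seeds (so coplanar landmark
    configurations are handled without a special-case linear initializer).
    Returns ``(pose, reprojection_rms_px, alignment_rms_mm, accepted)``
    where ``accepted`` applies the study's <1 mm alignment gate.
    """
    pixels = np.asarray(image_landmarks, dtype=float)
    points = np.asarray(surface_landmarks, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 2 or points.shape != (len(pixels), 3):
        raise ValueError("landmarks must be (N, 2) pixels paired with (N, 3) points")
    n = len(pixels)
    if n < 4:
        raise ValueError(f"at least 4 landmark pairs required, got {n}")
    spread = np.linalg.svd(points - points.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-6:
        raise ValueError("surface landmarks are collinear — pose is degenerate")

    centroid = points.mean(axis=0)
    scale = float(np.max(spread))
    candidates = []
    for rot in _ROTATION_SEEDS:
        t0 = np.array([0.0, 0.0, 3.0 * scale]) - rot @ centroid
        p0 = np.concatenate([Rotation.from_matrix(rot).as_rotvec(), t0])
        cost = 0.5 * np.sum(
            _reprojection_residuals(p0, pixels, points, intrinsics) ** 2
        )
        candidates.append((cost, p0))
    candidates.sort(key=lambda c: c[0])

    best = None
    for _, p0 in candidates[:6]:
        result = least_squares(
            _reprojection_residuals,
            p0,
            args=(pixels, points, intrinsics),
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
        )
        if best is None or result.cost < best.cost:
            best = result
    pose = RigidTransform(
        Rotation.from_rotvec(best.x[:3]).as_matrix(),
        best.x[3:],
        source="world",
        target="projector",
    )
    reproj = float(np.sqrt(np.mean(best.fun**2)))
    align = _ray_point_rms(pose, pixels, points, intrinsics)
    return pose, reproj, align, align < gate_mm


def landing_points(
    model: ProjectorModel,
    vertices_world: np.ndarray,
    skull_mesh: trimesh.Trimesh,
    world_to_skull: RigidTransform,
) -> LandingPointSet:
    """Cast a ray through each projected vertex onto the skull surface.

    ``skull_mesh`` lives in the skull reference frame; ``world_to_skull``
    is the tracked chain mapping world to that frame.  Each ray starts at
    the projector's optical center and passes through the vertex; the
    nearest positive-depth hit is the landing point, reported in the skull
    frame.  Rays that miss are flagged, not dropped.
    """
    verts = np.atleast_2d(np.asarray(vertices_world, dtype=float))
    pixels, _ = project_points(model, verts)
    center_world = model.pose.inverse().translation
    center_skull = world_to_skull.apply(center_world)
    dirs_world = verts - center_world
    norms = np.linalg.norm(dirs_world, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("a vertex coincides with the projector center")
    dirs_skull = (dirs_world / norms) @ world_to_skull.rotation.T

    n = len(verts)
    landing, hits = ray_mesh_first_hit(
        skull_mesh, np.tile(center_skull, (n, 1)), dirs_skull
    )
    return LandingPointSet(pixels, landing, hits)
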
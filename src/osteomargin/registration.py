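"""Rigid paired-point registration and frame bookkeeping.

Image-guided surgery chains several coordinate frames: the preoperative
image, the optical tracker ("world"), a reference body clamped to the
specimen, and tracked tools.  Everything here is a proper rigid motion in
millimetres, stored as a rotation matrix plus translation together with the
names of the frames it maps between, so that mis-ordered chain composition
is caught at run time instead of silently producing garbage poses.

The registration quality metric is the fiducial registration error (FRE):
the root-mean-square residual distance of the paired fiducials after the
least-squares alignment.  The study protocol accepts a registration only
when FRE <= 1 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "ToolCalibration",
    "fit_rigid",
    "gate_registration",
    "compose",
    "invert",
    "calibrate_tool",
]

_ORTHO_TOL = 1e-9


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthogonal")
    if np.linalg.det(rotation) < 0:
        raise ValueError("rotation matrix has det -1 (improper rotation)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion mapping points in ``source`` frame to ``target`` frame.

    Column-vector convention: ``p_target = R @ p_source + t``, units mm.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source: str = "source"
    target: str = "target"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, source: str = "source", target: str = "target") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source, target)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack (N, 3) from source to target frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.target, self.source)

    def as_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, source: str = "source", target: str = "target"
    ) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {matrix.shape}")
        return cls(matrix[:3, :3], matrix[:3, 3], source, target)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "target": self.target,
                "matrix": [float(v) for v in self.as_matrix().ravel()],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        obj = json.loads(text)
        matrix = np.array(obj["matrix"], dtype=float).reshape(4, 4)
        return cls.from_matrix(matrix, obj["source"], obj["target"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_json(fh.read())


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Return the chained transform "apply ``b``, then ``a``".

    Frame names must agree: ``b`` maps X -> Y and ``a`` maps Y -> Z, giving
    X -> Z.  A mismatch raises ``ValueError`` naming both frames.
    """
    if a.source != b.target:
        raise ValueError(
            f"cannot compose: inner transform targets frame {b.target!r} "
            f"but outer transform expects source frame {a.source!r}"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        b.source,
        a.target,
    )


def invert(a: RigidTransform) -> RigidTransform:
    return a.inverse()


def fit_rigid(
    source: np.ndarray,
    target: np.ndarray,
    source_frame: str = "source",
    target_frame: str = "target",
) -> tuple[RigidTransform, float]:
    """Least-squares rigid alignment of paired points (orthogonal Procrustes).

    Solves ``min_{R,t} sum_i || R s_i + t - q_i ||^2`` by SVD of the
    cross-covariance, with the standard reflection guard (the smallest
    singular direction is flipped when the unconstrained optimum is a
    reflection).  Returns the transform and the fiducial registration
    error, the RMS of the residual distances.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (N, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 point pairs required, got {n}")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    # Collinearity check: a degenerate configuration leaves rotation about
    # the line unconstrained.
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] < max(1e-6, 1e-9 * sv[0]):
        raise ValueError("fiducial configuration is collinear (rank < 2)")

    u, _, vt = np.linalg.svd(tgt_c.T @ src_c)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    t = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform(rot, t, source_frame, target_frame)
    residuals = transform.apply(src) - tgt
    fre = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, fre


def gate_registration(fre: float, limit: float = 1.0) -> bool:
    """Accept a registration iff FRE <= limit (the protocol gate, 1 mm)."""
    if fre < 0:
        raise ValueError(f"FRE must be non-negative, got {fre}")
    return fre <= limit


@dataclass(frozen=True)
class ToolCalibration:
    """Calibration of a tracked cutting tool in its marker frame.

    ``tip_offset`` locates the tool tip; ``blade_axis`` and ``blade_normal``
    give the osteotome blade's longitudinal axis and face normal, both unit
    vectors orthogonal to each other.
    """

    tip_offset: np.ndarray
    blade_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    blade_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        tip = np.asarray(self.tip_offset, dtype=float).reshape(3)
        axis = np.asarray(self.blade_axis, dtype=float).reshape(3)
        normal = np.asarray(self.blade_normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(axis) - 1) > 1e-9 or abs(np.linalg.norm(normal) - 1) > 1e-9:
            raise ValueError("blade axis and normal must be unit vectors")
        if abs(axis @ normal) > 1e-9:
            raise ValueError("blade axis must be orthogonal to blade normal")
        object.__setattr__(self, "tip_offset", tip)
        object.__setattr__(self, "blade_axis", axis)
        object.__setattr__(self, "blade_normal", normal)


def _rotation_spread_deg(rotations: list[np.ndarray]) -> float:
    """Largest relative rotation angle between any pose and the first."""
    r0 = rotations[0]
    worst = 0.0
    for r in rotations[1:]:
        rel = r0.T @ r
        cos = (np.trace(rel) - 1.0) / 2.0
        worst = max(worst, float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))))
    return worst


def calibrate_tool(
    poses: list[RigidTransform],
    blade_axis: np.ndarray = (0.0, 1.0, 0.0),
    blade_normal: np.ndarray = (0.0, 0.0, 1.0),
    min_poses: int = 10,
    min_spread_deg: float = 30.0,
) -> ToolCalibration:
    """Pivot calibration: recover the tip offset from poses while pivoting.

    While the tip rests in a fixed divot, each marker pose ``(R_i, p_i)``
    satisfies ``R_i x + p_i = c`` for the unknown tip offset ``x`` (marker
    frame) and pivot point ``c`` (world).  Stacking all poses gives a linear
    least-squares problem in ``(x, c)``.  Blade axes are a configured
    marker-frame convention, not estimated.
    """
    if len(poses) < min_poses:
        raise ValueError(f"need at least {min_poses} poses, got {len(poses)}")
    rotations = [p.rotation for p in poses]
    spread = _rotation_spread_deg(rotations)
    if spread < min_spread_deg:
        raise ValueError(
            f"insufficient orientation spread for pivot calibration: "
            f"{spread:.1f} deg < {min_spread_deg} deg (pivot unobservable)"
        )
    n = len(poses)
    a_mat = np.zeros((3 * n, 6))
    b_vec = np.zeros(3 * n)
    for i, pose in enumerate(poses):
        a_mat[3 * i : 3 * i + 3, :3] = pose.rotation
        a_mat[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b_vec[3 * i : 3 * i + 3] = -pose.translation
    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    tip, pivot = sol[:3], sol[3:]
    resid = np.array([pose.apply(tip) - pivot for pose in poses])
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return ToolCalibration(tip, np.asarray(blade_axis, float), np.asarray(blade_normal, float), rms)
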
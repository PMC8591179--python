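"""Tumor segmentation, surface extraction and signed distance fields.

The contouring workflow mirrors the semiautomatic protocol used on the CBCT
scans: a global intensity threshold gives the coarse mask, followed by a
deterministic morphological refinement (closing, hole filling, small-island
removal) standing in for interactive smoothing.  The tumor boundary is then
extracted as a triangulated isosurface, and a signed Euclidean distance
field — negative inside the tumor — makes "minimal distance to the tumor
surface" an O(1) trilinear query for the margin analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .phantom import Volume3D

__all__ = [
    "EmptySegmentationError",
    "SignedDistanceField",
    "segment_tumor",
    "extract_surface",
    "signed_distance",
    "query_distance",
]


class EmptySegmentationError(ValueError):
    """Raised when no voxel survives thresholding + refinement."""


def segment_tumor(
    volume: Volume3D, threshold: float, min_component_voxels: int = 100
) -> Volume3D:
    """Global threshold followed by morphological refinement.

    The mask is ``intensity >= threshold``, then: binary closing with a
    1-voxel ball, hole filling, and removal of connected components smaller
    than ``min_component_voxels``.  Raises :class:`EmptySegmentationError`
    rather than returning a silently empty mask.
    """
    lo, hi = float(volume.values.min()), float(volume.values.max())
    if not lo <= threshold <= hi:
        raise ValueError(f"threshold {threshold} outside intensity range [{lo}, {hi}]")
    mask = volume.values >= threshold
    if not mask.any():
        raise EmptySegmentationError(f"no voxels at or above threshold {threshold}")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connected ball, radius 1
    mask = ndimage.binary_closing(mask, structure=structure)
    mask = ndimage.binary_fill_holes(mask)
    labeled, n = ndimage.label(mask)
    if n:
        counts = np.bincount(labeled.ravel())
        keep = np.flatnonzero(counts >= min_component_voxels)
        keep = keep[keep != 0]
        mask = np.isin(labeled, keep)
    if not mask.any():
        raise EmptySegmentationError(
            "segmentation empty after refinement (all components below "
            f"{min_component_voxels} voxels)"
        )
    return Volume3D(mask.astype(np.int16), volume.spacing, volume.origin)


def extract_surface(label: Volume3D, level: float = 0.5) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary label volume, in mm coordinates.

    The label must not touch the volume border (the isosurface would be
    open there); pad the volume first if it does.  The returned mesh is
    watertight with outward-facing normals.
    """
    values = np.asarray(label.values)
    binary = values > 0
    if not binary.any():
        raise ValueError("label volume is empty; nothing to extract")
    border = (
        binary[0].any() or binary[-1].any()
        or binary[:, 0].any() or binary[:, -1].any()
        or binary[:, :, 0].any() or binary[:, :, -1].any()
    )
    if border:
        raise ValueError(
            "label touches the volume border; pad the volume before extracting "
            "a closed surface"
        )
    verts, faces, _, _ = measure.marching_cubes(
        binary.astype(np.float32), level=level, spacing=tuple(label.spacing)
    )
    verts = verts + label.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if not mesh.is_watertight:
        raise RuntimeError("extracted surface is not watertight")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


@dataclass
class SignedDistanceField:
    """Signed Euclidean distance (mm) to the tumor surface on the voxel grid.

    Negative inside the tumor, positive outside; the zero level set tracks
    the label boundary to within one voxel diagonal.
    """

    field: Volume3D

    @property
    def spacing(self) -> np.ndarray:
        return self.field.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.field.origin


def signed_distance(label: Volume3D) -> SignedDistanceField:
    """Compose inside/outside Euclidean distance transforms into one field.

    Each transform measures to the nearest voxel *center* of the opposite
    phase, which puts the raw zero crossing half a voxel inside the mask;
    both sides are therefore shifted half a (mean) voxel toward the
    inside/outside interface so the zero level set coincides with the
    marching-cubes 0.5 isosurface.
    """
    mask = np.asarray(label.values) > 0
    if not mask.any():
        raise ValueError("label volume is empty; distance field undefined")
    spacing = label.spacing
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    half = float(np.mean(spacing)) / 2.0
    signed = np.where(mask, -(inside - half), outside - half)
    return SignedDistanceField(Volume3D(signed, spacing, label.origin))


def query_distance(field: SignedDistanceField, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the signed distance at world-mm points.

    Accepts one point (3,) or a stack (N, 3).  Points outside the sampled
    grid raise ``ValueError`` — the field does not extrapolate.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vol = field.field
    idx = vol.world_to_index(pts)
    upper = np.array(vol.shape, dtype=float) - 1.0
    bad = np.any((idx < -1e-9) | (idx > upper + 1e-9), axis=1)
    if bad.any():
        offender = pts[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"query point {tuple(np.round(offender, 3))} lies outside the "
            "distance-field volume"
        )
    out = ndimage.map_coordinates(
        vol.values, np.clip(idx, 0, upper).T, order=1, mode="nearest"
    )
    if np.asarray(points).ndim == 1:
        return float(out[0])
    return out
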
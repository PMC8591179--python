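"""Exact mesh geometry queries: ray casting and point-to-surface distance.

Brute-force, fully vectorized implementations over all triangles.  The
voxelized signed distance field is the production path for margin scoring;
these exact queries serve as its independent oracle, as the ray caster for
projector landing points, and as the scorer for the rare cut plane that
leaves the field volume.  Complexity is O(points x faces), chunked to
bound memory, which is ample at this package's mesh sizes.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = ["ray_mesh_first_hit", "point_mesh_distance", "signed_point_mesh_distance"]

_EPS = 1e-12


def ray_mesh_first_hit(
    mesh: trimesh.Trimesh,
    origins: np.ndarray,
    directions: np.ndarray,
    min_t: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """First positive-depth ray-triangle hit per ray (Moller-Trumbore).

    Returns ``(points, hit)``: intersection points (NaN where no hit) and a
    boolean hit mask.  ``directions`` need not be normalized; hits at ray
    parameter below ``min_t`` (behind or at the origin) are ignored.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = mesh.triangles  # (F, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0

    n_rays = len(origins)
    best_t = np.full(n_rays, np.inf)
    for i in range(n_rays):
        d = directions[i]
        o = origins[i]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > _EPS
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, qvec) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        ok &= (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > min_t)
        if ok.any():
            best_t[i] = t[ok].min()

    hit = np.isfinite(best_t)
    points = np.full((n_rays, 3), np.nan)
    points[hit] = origins[hit] + best_t[hit, None] * directions[hit]
    return points, hit


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance of each point to any triangle; points (P,3), tri (F,3,3)."""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e0 = v1 - v0  # (F, 3)
    e1 = v2 - v0
    a = np.einsum("ij,ij->i", e0, e0)
    b = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)

    diff = v0[None, :, :] - points[:, None, :]  # (P, F, 3)
    d = np.einsum("pfj,fj->pf", diff, e0)
    e = np.einsum("pfj,fj->pf", diff, e1)
    det = np.maximum(a * c - b * b, _EPS)
    s = (b * e - c * d) / det
    t = (b * d - a * e) / det

    # The closest point on a triangle is either the orthogonal projection
    # onto its plane (when that projection lands inside the triangle) or a
    # point on one of the three edge segments; the minimum over those four
    # candidates is exact.
    def edge_dist(p0, edge):
        rel = points[:, None, :] - p0[None, :, :]
        ee = np.einsum("fj,fj->f", edge, edge)
        proj = np.clip(np.einsum("pfj,fj->pf", rel, edge) / np.maximum(ee, _EPS), 0.0, 1.0)
        foot = p0[None, :, :] + proj[:, :, None] * edge[None, :, :]
        return np.linalg.norm(points[:, None, :] - foot, axis=2)

    cand = edge_dist(v0, e0)
    cand = np.minimum(cand, edge_dist(v0, e1))
    cand = np.minimum(cand, edge_dist(v1, v2 - v1))

    interior = (s >= 0) & (t >= 0) & (s + t <= 1)
    if np.any(interior):
        normal = np.cross(e0, e1)
        nn = np.linalg.norm(normal, axis=1)
        plane_d = np.abs(np.einsum("pfj,fj->pf", -diff, normal)) / np.maximum(nn, _EPS)
        cand = np.where(interior, np.minimum(cand, plane_d), cand)
    return cand.min(axis=1)


def point_mesh_distance(
    mesh: trimesh.Trimesh, points: np.ndarray, chunk: int = 256
) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        sl = slice(start, start + chunk)
        out[sl] = _point_triangle_distances(points[sl], tri)
    return out


def signed_point_mesh_distance(
    mesh: trimesh.Trimesh, points: np.ndarray, chunk: int = 256
) -> np.ndarray:
    """Signed distance: negative inside the (watertight) mesh.

    Sign by ray-crossing parity along a fixed direction chosen away from
    axis alignment to dodge edge-grazing degeneracies.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dist = point_mesh_distance(mesh, points, chunk)
    direction = np.array([0.577350269189626, 0.577350269189626, 0.577350269189626])
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok0 = np.abs(det) > _EPS
    inv_det = np.where(ok0, 1.0 / np.where(ok0, det, 1.0), 0.0)
    inside = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        tvec = p - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", direction, qvec) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        hits = ok0 & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > _EPS)
        inside[i] = hits.sum() % 2 == 1
    return np.where(inside, -dist, dist)
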
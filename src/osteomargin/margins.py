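"""Cut-plane margin scoring: the study's primary outcome computation.

For every recorded osteotome pose, a 4 cm x 2 cm region of the cut plane
(2 cm on both ends along the blade's longitudinal axis, 1 cm on both sides
across it) is sampled on a regular grid, the minimal signed distance to the
tumor surface is looked up at every grid point, and each point is classified
into the margin bins

    intratumoral  d <= 0 mm
    close         0 < d <= 5 mm
    adequate      5 < d <= 15 mm
    excessive     d > 15 mm

A cut is flagged intratumoral when any of its points enters the tumor
(distance <= 0); per-cut bin percentages, the minimum distance, and the
flag form the unit of the downstream contingency analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps, colors
from PIL import Image

from .behavior import CutRecord
from .segmentation import SignedDistanceField, query_distance

__all__ = [
    "MARGIN_BINS",
    "PlaneRegion",
    "DistanceMap",
    "MarginSummary",
    "classify_distance",
    "classify_distances",
    "plane_region_from_cut",
    "sample_distances",
    "summarize",
    "render_distance_map",
    "score_cut",
    "summaries_to_frame",
]

MARGIN_BINS = ("intratumoral", "close", "adequate", "excessive")
_BIN_EDGES = (0.0, 5.0, 15.0)  # mm; upper bounds, inclusive

HALF_LENGTH_MM = 20.0  # along the longitudinal axis u (4 cm total)
HALF_WIDTH_MM = 10.0  # across it (2 cm total)


def classify_distance(d: float) -> str:
    """Margin bin of a single signed distance (upper bounds inclusive)."""
    if not np.isfinite(d):
        raise ValueError(f"distance must be finite, got {d}")
    if d <= _BIN_EDGES[0]:
        return "intratumoral"
    if d <= _BIN_EDGES[1]:
        return "close"
    if d <= _BIN_EDGES[2]:
        return "adequate"
    return "excessive"


def classify_distances(d: np.ndarray) -> np.ndarray:
    """Vectorized margin binning; returns an array of bin names."""
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    idx = np.searchsorted(_BIN_EDGES, d, side="left")
    return np.asarray(MARGIN_BINS)[idx]


@dataclass(frozen=True)
class PlaneRegion:
    """The scored 4 x 2 cm rectangle of a cut plane."""

    origin: np.ndarray
    u: np.ndarray  # longitudinal axis, unit
    v: np.ndarray  # width axis = normal x u, unit
    step: float = 0.5

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        u = np.asarray(self.u, dtype=float).reshape(3)
        v = np.asarray(self.v, dtype=float).reshape(3)
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise ValueError("region axes must be unit vectors")
        if abs(u @ v) > 1e-9:
            raise ValueError("region axes must be orthogonal")
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def grid_points(self) -> np.ndarray:
        """3D sample points, shape (n_u, n_v, 3); rows run along u."""
        su = np.arange(-HALF_LENGTH_MM, HALF_LENGTH_MM + self.step / 2, self.step)
        sv = np.arange(-HALF_WIDTH_MM, HALF_WIDTH_MM + self.step / 2, self.step)
        return (
            self.origin
            + su[:, None, None] * self.u
            + sv[None, :, None] * self.v
        )

    def corners(self) -> np.ndarray:
        s = np.array(
            [
                [-HALF_LENGTH_MM, -HALF_WIDTH_MM],
                [-HALF_LENGTH_MM, HALF_WIDTH_MM],
                [HALF_LENGTH_MM, -HALF_WIDTH_MM],
                [HALF_LENGTH_MM, HALF_WIDTH_MM],
            ]
        )
        return self.origin + s[:, :1] * self.u + s[:, 1:] * self.v


@dataclass(frozen=True)
class DistanceMap:
    """Signed distances (mm) sampled on a plane region's grid."""

    values: np.ndarray  # (n_u, n_v)
    step: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("distance map must be a non-empty 2D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance map contains non-finite values")
        object.__setattr__(self, "values", values)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6f")


@dataclass(frozen=True)
class MarginSummary:
    """Per-cut margin score: bin percentages, minimum distance, flag."""

    fractions: dict[str, float]  # percent, keyed by MARGIN_BINS
    min_distance: float  # mm
    intratumoral: bool

    def __post_init__(self) -> None:
        total = sum(self.fractions[b] for b in MARGIN_BINS)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"bin percentages must sum to 100, got {total}")
        if self.intratumoral != (self.min_distance <= 0):
            raise ValueError("intratumoral flag must equal (min distance <= 0)")


def plane_region_from_cut(cut: CutRecord, step: float = 0.5) -> PlaneRegion:
    """Region centered at the recorded osteotome origin, rows along the blade."""
    u = np.asarray(cut.longitudinal_axis, dtype=float)
    normal = np.asarray(cut.normal, dtype=float)
    return PlaneRegion(np.asarray(cut.origin, dtype=float), u, np.cross(normal, u), step)


def sample_distances(region: PlaneRegion, field: SignedDistanceField) -> DistanceMap:
    """Query the signed distance field at every region grid point."""
    pts = region.grid_points()
    try:
        values = query_distance(field, pts.reshape(-1, 3))
    except ValueError:
        for corner in region.corners():
            try:
                query_distance(field, corner)
            except ValueError:
                raise ValueError(
                    f"plane region corner {tuple(np.round(corner, 2))} exits the "
                    "distance-field volume"
                ) from None
        raise
    return DistanceMap(values.reshape(pts.shape[:2]), region.step)


def summarize(distance_map: DistanceMap) -> MarginSummary:
    """Bin percentages over all grid points plus the intratumoral flag."""
    d = distance_map.values.ravel()
    bins = classify_distances(d)
    fractions = {b: 100.0 * float(np.mean(bins == b)) for b in MARGIN_BINS}
    # Remove floating residue so the partition sums to exactly 100.
    residue = 100.0 - sum(fractions.values())
    fractions[MARGIN_BINS[-1]] += residue
    min_d = float(d.min())
    return MarginSummary(fractions, min_d, bool(min_d <= 0))


def score_cut(
    cut: CutRecord, field: SignedDistanceField, step: float = 0.5
) -> tuple[DistanceMap, MarginSummary]:
    """Convenience: region -> distance map -> summary for one cut."""
    dmap = sample_distances(plane_region_from_cut(cut, step), field)
    return dmap, summarize(dmap)


def _normalize_for_render(values: np.ndarray) -> np.ndarray:
    # Piecewise-linear ramp anchored at the bin edges 0 / 5 / 15 mm so the
    # color scale is fixed across maps regardless of their value range.
    anchors_mm = np.array([-15.0, 0.0, 5.0, 15.0, 30.0])
    anchors_unit = np.array([0.0, 0.35, 0.55, 0.8, 1.0])
    return np.interp(values, anchors_mm, anchors_unit)


def render_distance_map(distance_map: DistanceMap, path, upscale: int = 8) -> None:
    """Write the color-scaled margin image (PNG, deterministic bytes).

    Diverging colormap anchored at the tumor boundary (0 mm) and the 5 and
    15 mm bin edges; red = intratumoral, green/blue = safe margins.
    """
    cmap = colormaps["RdYlBu"]
    rgba = cmap(_normalize_for_render(distance_map.values))
    img = (np.asarray(rgba)[:, :, :3] * 255).round().astype(np.uint8)
    # Transpose so the long (longitudinal) axis runs horizontally.
    img = np.transpose(img, (1, 0, 2))
    if upscale > 1:
        img = np.repeat(np.repeat(img, upscale, axis=0), upscale, axis=1)
    Image.fromarray(img).save(path, format="PNG")


def summaries_to_frame(records: list[tuple[CutRecord, MarginSummary]]) -> pd.DataFrame:
    """Tabulate per-cut summaries for the statistics layer."""
    rows = []
    for cut, summary in records:
        row = {
            "surgeon_id": cut.surgeon_id,
            "tumor_id": cut.tumor_id,
            "site_id": cut.site_id,
            "condition": cut.condition.value,
            "duration_s": cut.duration_s,
            "min_distance_mm": summary.min_distance,
            "intratumoral": summary.intratumoral,
        }
        for b in MARGIN_BINS:
            row[f"pct_{b}"] = summary.fractions[b]
        rows.append(row)
    return pd.DataFrame(rows)
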
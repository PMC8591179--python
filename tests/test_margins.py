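"""Margin scoring: binning, plane sampling, summaries, rendering.

Closed-form oracles: point-to-sphere distance, disc areas of plane-sphere
intersections, and exact brute-force point-to-mesh distance.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteomargin.margins import (
    MARGIN_BINS,
    DistanceMap,
    PlaneRegion,
    classify_distance,
    classify_distances,
    plane_region_from_cut,
    render_distance_map,
    sample_distances,
    summarize,
)
from osteomargin.behavior import ConditionNoise, simulate_cut
from osteomargin.meshdist import signed_point_mesh_distance
from osteomargin.phantom import OsteotomySite
from osteomargin.segmentation import extract_surface, signed_distance
from tests.conftest import make_sphere_label


def xy_region(z, step=0.5):
    return PlaneRegion(
        np.array([0.0, 0.0, float(z)]),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        step,
    )


class TestClassifyDistance:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (-2.0, "intratumoral"),
            (0.0, "intratumoral"),
            (1e-9, "close"),
            (5.0, "close"),
            (5.0001, "adequate"),
            (15.0, "adequate"),
            (15.0001, "excessive"),
            (40.0, "excessive"),
        ],
    )
    def test_bin_boundaries_inclusive_above(self, d, expected):
        assert classify_distance(d) == expected
        assert classify_distances(np.array([d]))[0] == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_distance(np.nan)
        with pytest.raises(ValueError):
            classify_distances(np.array([1.0, np.inf]))


class TestPlaneSampling:
    def test_grid_shape_and_planarity(self):
        region = xy_region(15.0)
        pts = region.grid_points()
        assert pts.shape == (81, 41, 3)
        offsets = (pts - region.origin) @ region.normal
        assert np.abs(offsets).max() < 1e-9

    def test_sphere_plane_z15_matches_closed_form(self, sphere_sdf, voxel_diagonal):
        dmap = sample_distances(xy_region(15.0), sphere_sdf)
        su = np.arange(-20, 20.25, 0.5)
        sv = np.arange(-10, 10.25, 0.5)
        xx, yy = np.meshgrid(su, sv, indexing="ij")
        exact = np.sqrt(xx**2 + yy**2 + 225.0) - 10.0
        assert np.abs(dmap.values - exact).max() <= voxel_diagonal
        assert dmap.values[40, 20] == pytest.approx(5.0, abs=voxel_diagonal)

    def test_plane_through_center_reaches_minus_radius(self, sphere_sdf, voxel_diagonal):
        dmap = sample_distances(xy_region(0.0), sphere_sdf)
        assert dmap.values[40, 20] == pytest.approx(-10.0, abs=voxel_diagonal)

    def test_region_exiting_volume_names_corner(self, sphere_sdf):
        with pytest.raises(ValueError, match="corner"):
            sample_distances(xy_region(25.0), sphere_sdf)

    def test_region_from_cut_axes(self):
        from osteomargin.behavior import CutRecord, GuidanceCondition

        rec = CutRecord(
            1, 1, "Zy", GuidanceCondition.AR,
            (1.0, 2.0, 3.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
        )
        region = plane_region_from_cut(rec, 0.5)
        assert np.allclose(region.u, [0, 1, 0])
        assert np.allclose(region.v, np.cross([0, 0, 1], [0, 1, 0]))


class TestSummarize:
    def test_uniform_adequate_map(self):
        summary = summarize(DistanceMap(np.full((81, 41), 10.0), 0.5))
        assert summary.fractions["adequate"] == 100.0
        assert not summary.intratumoral

    def test_intratumoral_fraction_matches_disc_area(self, sphere_sdf):
        # Plane z = 5 cuts the radius-10 sphere in a disc of radius
        # sqrt(75); its area over the 40 x 20 mm region is 29.45%.
        summary = summarize(sample_distances(xy_region(5.0), sphere_sdf))
        analytic = 100.0 * np.pi * 75.0 / 800.0
        assert summary.intratumoral
        assert summary.fractions["intratumoral"] == pytest.approx(analytic, abs=1.5)

    def test_far_plane_has_no_close_or_intratumoral_points(self, sphere_sdf):
        summary = summarize(sample_distances(xy_region(20.0), sphere_sdf))
        # min distance sqrt(400) - 10 = 10 at center; all points adequate+
        assert summary.fractions["intratumoral"] == 0.0
        assert summary.fractions["close"] == 0.0
        assert summary.min_distance == pytest.approx(10.0, abs=0.9)

    def test_single_point_counting(self):
        values = np.full((81, 41), 10.0)
        values[0, 0] = -0.001
        summary = summarize(DistanceMap(values, 0.5))
        assert summary.intratumoral
        assert summary.fractions["intratumoral"] == pytest.approx(100.0 / 3321.0)

    @given(
        st.lists(
            st.floats(min_value=-30.0, max_value=50.0, allow_nan=False),
            min_size=4,
            max_size=200,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_fractions_partition_to_100(self, values):
        n = (len(values) // 2) * 2
        arr = np.asarray(values[:n], dtype=float).reshape(2, -1)
        summary = summarize(DistanceMap(arr, 0.5))
        assert sum(summary.fractions.values()) == pytest.approx(100.0, abs=1e-9)

    def test_translating_plane_away_never_increases_intratumoral(self, sphere_sdf):
        fracs = [
            summarize(sample_distances(xy_region(z), sphere_sdf)).fractions[
                "intratumoral"
            ]
            for z in (0.0, 4.0, 8.0, 12.0, 16.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestFieldVsExactMeshOracle:
    def test_random_ellipsoid_meshes_agree_with_brute_force(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            radii = rng.uniform(5.0, 11.0, 3)
            label = make_sphere_label(radius=1.0, spacing=0.5, half_extent=16.0)
            g = np.arange(-16.0, 16.25, 0.5)
            r2 = (
                ((g / radii[0]) ** 2)[:, None, None]
                + ((g / radii[1]) ** 2)[None, :, None]
                + ((g / radii[2]) ** 2)[None, None, :]
            )
            label.values[:] = (r2 <= 1.0).astype(np.int16)
            sdf = signed_distance(label)
            mesh = extract_surface(label)
            pts = rng.uniform(-14, 14, (150, 3))
            exact = signed_point_mesh_distance(mesh, pts)
            from osteomargin.segmentation import query_distance

            approx = query_distance(sdf, pts)
            assert np.abs(exact - approx).max() <= np.sqrt(3) * 0.5


class TestRender:
    def test_deterministic_bytes_and_uniform_color(self, tmp_path):
        dmap = DistanceMap(np.full((81, 41), 10.0), 0.5)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_distance_map(dmap, p1)
        render_distance_map(dmap, p2)
        assert p1.read_bytes() == p2.read_bytes()
        from PIL import Image

        img = np.asarray(Image.open(p1))
        assert (img.reshape(-1, img.shape[-1]) == img.reshape(-1, img.shape[-1])[0]).all()

    def test_monotone_gradient_monotone_color(self, tmp_path):
        from osteomargin.margins import _normalize_for_render

        values = np.tile(np.linspace(-15, 30, 81)[:, None], (1, 41))
        # The value -> colormap position mapping is strictly monotone, so a
        # monotone distance gradient renders as a monotone color progression.
        norm = _normalize_for_render(values[:, 0])
        assert np.all(np.diff(norm) > 0)
        path = tmp_path / "grad.png"
        render_distance_map(DistanceMap(values, 0.5), path, upscale=1)
        from PIL import Image

        img = np.asarray(Image.open(path)).astype(int)
        colors_along_gradient = {tuple(c) for c in img[0]}
        assert len(colors_along_gradient) > 40
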
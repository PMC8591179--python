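"""Projector geometry: pinhole model, pose registration, landing points."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from osteomargin.projection import (
    LandingPointSet,
    ProjectorIntrinsics,
    ProjectorModel,
    landing_points,
    project_points,
    register_projector,
)
from osteomargin.registration import RigidTransform


INTR = ProjectorIntrinsics(fx=1500.0, fy=1500.0, cx=960.0, cy=540.0)


@pytest.fixture(scope="module")
def true_pose():
    rot = Rotation.from_euler("xyz", [5, -10, 3], degrees=True).as_matrix()
    return RigidTransform(rot, np.array([20.0, -10.0, 500.0]), "world", "projector")


@pytest.fixture(scope="module")
def model(true_pose):
    return ProjectorModel(INTR, true_pose)


@pytest.fixture(scope="module")
def skull_sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=55.0)


class TestProjectPoints:
    def test_optical_axis_hits_principal_point(self):
        model = ProjectorModel(INTR, RigidTransform.identity("world", "projector"))
        pix, ok = project_points(model, np.array([[0.0, 0.0, 300.0]]))
        assert ok[0]
        assert pix[0] == pytest.approx([960.0, 540.0])

    def test_lateral_offset_closed_form(self):
        model = ProjectorModel(INTR, RigidTransform.identity("world", "projector"))
        pix, _ = project_points(model, np.array([[20.0, 0.0, 400.0]]))
        assert pix[0, 0] == pytest.approx(1500.0 * 20.0 / 400.0 + 960.0)

    def test_perspective_halving(self):
        model = ProjectorModel(INTR, RigidTransform.identity("world", "projector"))
        pix, _ = project_points(
            model, np.array([[20.0, 0.0, 400.0], [20.0, 0.0, 800.0]])
        )
        off = pix[:, 0] - 960.0
        assert off[1] == pytest.approx(off[0] / 2.0)

    def test_behind_projector_flagged_not_dropped(self):
        model = ProjectorModel(INTR, RigidTransform.identity("world", "projector"))
        pix, ok = project_points(model, np.array([[0.0, 0.0, -100.0], [0.0, 0.0, 100.0]]))
        assert list(ok) == [False, True]
        assert np.isnan(pix[0]).all()


class TestRegisterProjector:
    def landmarks(self, true_pose, n=8, seed=0, coplanar=False):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-80.0, 80.0, (n, 3))
        pts[:, 2] = 0.0 if coplanar else pts[:, 2] * 0.3
        model = ProjectorModel(INTR, true_pose)
        pix, ok = project_points(model, pts)
        assert ok.all()
        return pix, pts

    def test_noiseless_recovery(self, true_pose):
        pix, pts = self.landmarks(true_pose)
        pose, reproj, align, accepted = register_projector(pix, pts, INTR)
        assert np.abs(pose.as_matrix() - true_pose.as_matrix()).max() < 1e-6
        assert reproj < 1e-6
        assert align < 1e-6
        assert accepted

    def test_coplanar_landmarks_handled(self, true_pose):
        pix, pts = self.landmarks(true_pose, coplanar=True)
        pose, _, align, _ = register_projector(pix, pts, INTR)
        assert align < 1e-6

    def test_three_landmarks_rejected(self, true_pose):
        pix, pts = self.landmarks(true_pose)
        with pytest.raises(ValueError, match="at least 4"):
            register_projector(pix[:3], pts[:3], INTR)

    def test_collinear_landmarks_rejected(self, true_pose):
        pts = np.outer(np.linspace(-50, 50, 6), [1.0, 0.3, 0.0])
        model = ProjectorModel(INTR, true_pose)
        pix, _ = project_points(model, pts)
        with pytest.raises(ValueError, match="degenerate"):
            register_projector(pix, pts, INTR)

    def test_pixel_noise_alignment_gate(self, true_pose):
        # Study gate: AR registration error < 1 mm; at 0.5 px pixel noise
        # and ~500 mm scene depth the gate passes in >= 95% of trials.
        pix, pts = self.landmarks(true_pose)
        passed = 0
        trials = 200
        for seed in range(trials):
            noisy = pix + np.random.default_rng(seed).normal(0.0, 0.5, pix.shape)
            _, _, align, accepted = register_projector(noisy, pts, INTR)
            passed += accepted
        assert passed / trials >= 0.95

    def test_alignment_error_monotone_in_pixel_noise(self, true_pose):
        pix, pts = self.landmarks(true_pose)
        means = []
        for sd in (0.2, 1.0, 4.0):
            errs = [
                register_projector(
                    pix + np.random.default_rng(seed).normal(0.0, sd, pix.shape),
                    pts,
                    INTR,
                )[2]
                for seed in range(30)
            ]
            means.append(np.mean(errs))
        assert means == sorted(means)


def facing_vertices(mesh, center, count, seed=1, min_dot=30.0):
    rng = np.random.default_rng(seed)
    verts = mesh.vertices
    facing = verts @ (center / np.linalg.norm(center)) > min_dot
    idx = rng.choice(np.flatnonzero(facing), count, replace=False)
    return verts[idx]


class TestLandingPoints:
    def test_ray_sphere_closed_form(self, model, true_pose, skull_sphere):
        lp = landing_points(
            model,
            np.array([[0.0, 0.0, 0.0]]),
            skull_sphere,
            RigidTransform.identity("world", "skull"),
        )
        center = true_pose.inverse().translation
        d = -center / np.linalg.norm(center)
        b = 2.0 * center @ d
        c = center @ center - 55.0**2
        s = (-b - np.sqrt(b * b - 4.0 * c)) / 2.0
        expected = center + s * d
        # Tolerance covers the icosphere facet sagitta vs the true sphere.
        assert lp.hit[0]
        assert np.abs(lp.points_skull[0] - expected).max() < 0.5

    def test_reprojecting_landing_point_returns_pixel(self, model, skull_sphere, true_pose):
        center = true_pose.inverse().translation
        verts = facing_vertices(skull_sphere, center, 10)
        lp = landing_points(
            model, verts, skull_sphere, RigidTransform.identity("world", "skull")
        )
        pix_again, _ = project_points(model, lp.points_skull)
        assert np.abs(pix_again - lp.pixels).max() < 1e-6

    def test_skull_repositioning_invariance(self, model, skull_sphere, true_pose):
        center = true_pose.inverse().translation
        verts = facing_vertices(skull_sphere, center, 20)
        identity = RigidTransform.identity("world", "skull")
        lp0 = landing_points(model, verts, skull_sphere, identity)
        motion_r = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        motion_t = np.array([30.0, 5.0, -10.0])
        w2s_new = RigidTransform(motion_r, motion_t, "skull", "world").inverse()
        lp1 = landing_points(
            model, verts @ motion_r.T + motion_t, skull_sphere, w2s_new
        )
        assert np.nanmax(np.abs(lp1.points_skull - lp0.points_skull)) < 1e-6

    def test_projector_repositioning_invariance(self, model, skull_sphere, true_pose):
        center = true_pose.inverse().translation
        verts = facing_vertices(skull_sphere, center, 20)
        identity = RigidTransform.identity("world", "skull")
        lp0 = landing_points(model, verts, skull_sphere, identity)
        motion_r = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        motion = np.eye(4)
        motion[:3, :3] = motion_r
        motion[:3, 3] = [-60.0, 30.0, 40.0]
        moved = ProjectorModel(
            INTR,
            RigidTransform.from_matrix(
                true_pose.as_matrix() @ np.linalg.inv(motion), "world", "projector"
            ),
        )
        lp1 = landing_points(moved, verts, skull_sphere, identity)
        assert np.nanmax(np.abs(lp1.points_skull - lp0.points_skull)) < 1e-6

    def test_oblique_plane_footprint_stretches_by_sec_theta(self):
        # A square projected onto a plane tilted by theta stretches by
        # 1 / cos(theta) along the tilt axis.
        theta = np.radians(35.0)
        plane = trimesh.creation.box(extents=(4000.0, 4000.0, 0.1))
        rot = Rotation.from_euler("x", theta).as_matrix()
        plane.apply_transform(
            np.vstack([np.hstack([rot, [[0], [0], [800.0]]]), [0, 0, 0, 1]])
        )
        model = ProjectorModel(INTR, RigidTransform.identity("world", "projector"))
        # Vertices of a small square at depth just in front of the plane.
        half = 10.0
        square = np.array(
            [[-half, -half, 700.0], [half, -half, 700.0],
             [-half, half, 700.0], [half, half, 700.0]]
        )
        lp = landing_points(
            model, square, plane, RigidTransform.identity("world", "skull")
        )
        assert lp.hit.all()
        landed = lp.points_skull
        width = np.linalg.norm(landed[1] - landed[0])  # along untilted x
        height = np.linalg.norm(landed[2] - landed[0])  # along tilt axis
        # remove the perspective scale shared by both axes
        assert height / width == pytest.approx(1.0 / np.cos(theta), rel=0.02)

    def test_miss_flagged(self, model, skull_sphere):
        lp = landing_points(
            model,
            np.array([[2000.0, 0.0, 0.0]]),
            skull_sphere,
            RigidTransform.identity("world", "skull"),
        )
        assert not lp.hit[0]
        assert np.isnan(lp.points_skull[0]).all()
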
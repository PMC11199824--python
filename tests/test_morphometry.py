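"""Feature tests: Jacobians, deformation tensors, MAD, the combined field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccmorph import (
    CohortConfig,
    GridSurface,
    deformation_tensor,
    feature_field,
    mad_field,
    make_medial_curve,
    make_tube_surface,
    medial_axis,
    parameterize_mesh,
    sample_subject,
    triangle_jacobian,
    RadiusProfile,
)
from ccmorph.mesh import GeometryError
from ccmorph.morphometry import arclength_fractions, window_rows
from ccmorph.synthetic import default_radius_profile

from conftest import cylinder_mesh


def _rot3(deg, axis):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.deg2rad(deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


tri_strategy = st.lists(
    st.floats(-10, 10, allow_nan=False, width=32), min_size=18, max_size=18
).map(lambda v: np.array(v, float).reshape(2, 3, 3)).filter(
    lambda t: min(
        np.linalg.norm(np.cross(t[i, 1] - t[i, 0], t[i, 2] - t[i, 0])) / 2
        for i in range(2)
    ) > 1e-3
)


class TestTriangleJacobian:
    def test_identity_scale_and_shear(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        assert np.allclose(triangle_jacobian(src, src), np.eye(2), atol=1e-12)

        J = triangle_jacobian(src, 2.0 * src)
        assert np.allclose(J, 2 * np.eye(2), atol=1e-12)
        assert np.isclose(np.linalg.det(J), 4.0)

        shear_tgt = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        J = triangle_jacobian(src, shear_tgt)
        assert np.allclose(J, [[1, 1], [0, 1]], atol=1e-12)
        assert np.isclose(np.linalg.det(J), 1.0)

    def test_degenerate_triangle_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        tgt = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(GeometryError):
            triangle_jacobian(src, tgt)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(tri_strategy)
    def test_det_equals_area_ratio(self, tris):
        src, tgt = tris
        J = triangle_jacobian(src, tgt)
        area = lambda t: 0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0]))
        assert abs(abs(np.linalg.det(J)) - area(tgt) / area(src)) < 1e-9 * area(tgt) / area(src) + 1e-9


class TestDeformationTensor:
    def test_closed_forms(self):
        s, l3 = deformation_tensor(np.eye(2))
        assert np.allclose(s, np.eye(2))
        assert np.allclose(l3, 0.0)

        _, l3 = deformation_tensor(np.diag([2.0, 3.0]))
        assert np.allclose(l3, [np.log(2), 0.0, np.log(3)], atol=1e-12)

        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degrees
        s, l3 = deformation_tensor(rot)
        assert np.allclose(s, np.eye(2), atol=1e-12)
        assert np.allclose(l3, 0.0, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-3, 3, allow_nan=False, width=32), min_size=4,
                    max_size=4).map(lambda v: np.array(v).reshape(2, 2)).filter(
                        lambda j: np.linalg.det(j) > 1e-3))
    def test_square_root_and_rotation_invariance(self, J):
        s, l3 = deformation_tensor(J)
        assert np.abs(s @ s - J.T @ J).max() < 1e-9
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        s2, l32 = deformation_tensor(rot @ J)
        assert np.abs(s - s2).max() < 1e-9
        assert np.abs(l3 - l32).max() < 1e-9
        # logS3 == 0 iff the map is a rigid motion
        if np.abs(l3).max() < 1e-12:
            assert np.abs(J.T @ J - np.eye(2)).max() < 1e-9


class TestMedialAxisAndMad:
    def test_cylinder_axis_and_mad(self, straight_cylinder):
        grid = parameterize_mesh(straight_cylinder, (16, 8))
        axis = medial_axis(grid)
        assert np.abs(axis.points[:, 1:]).max() < 1e-6
        mad = mad_field(grid, axis)
        assert np.abs(mad - 5.0).max() < 1e-6

    def test_axis_matches_generator_curve(self):
        cfg = CohortConfig(noise_sd=0.0, scale_jitter_sd=0.0,
                           rigid_rot_deg=0.0, rigid_trans_mm=0.0)
        grid = parameterize_mesh(sample_subject(cfg, "A", 1), (64, 16))
        axis = medial_axis(grid)
        fine = make_medial_curve(2048, cfg.arch_height, cfg.length)
        from scipy.spatial import cKDTree
        dist, _ = cKDTree(fine.points).query(axis.points)
        assert dist.max() < 0.02 * axis.arc_length()

    def test_axis_rigid_equivariance(self, arched_mesh):
        grid = parameterize_mesh(arched_mesh, (32, 8))
        rot = _rot3(30, (0, 1, 0))
        moved = GridSurface(grid.points @ rot.T + np.array([1.0, 2.0, 3.0]))
        ax = medial_axis(grid)
        ax2 = medial_axis(moved)
        assert np.abs(ax2.points - (ax.points @ rot.T + [1, 2, 3])).max() < 1e-9

    def test_linear_radius_tube_mad(self):
        curve = make_medial_curve(64, 0.0, 100.0)
        t = np.linspace(0, 1, 32)
        prof = RadiusProfile(t, np.arange(8) * np.pi / 4,
                             np.outer(3.0 + 2.0 * t, np.ones(8)))
        mesh = make_tube_surface(curve, prof, (64, 16))
        grid = parameterize_mesh(mesh, (32, 8))
        mad = mad_field(grid, medial_axis(grid))
        frac = arclength_fractions(medial_axis(grid))
        expected = 3.0 + 2.0 * frac
        rel = np.abs(mad.mean(axis=1) - expected) / expected
        assert rel.max() < 0.02

    def test_mad_recovers_ground_truth_profile(self):
        cfg = CohortConfig(noise_sd=0.0, scale_jitter_sd=0.0,
                           rigid_rot_deg=0.0, rigid_trans_mm=0.0,
                           ellipticity=0.0)
        grid = parameterize_mesh(sample_subject(cfg, "A", 1), (64, 16))
        mad = mad_field(grid, medial_axis(grid))
        prof = default_radius_profile(ellipticity=0.0)
        frac = arclength_fractions(medial_axis(grid))
        gt = prof(frac, np.zeros_like(frac))
        assert (np.abs(mad.mean(axis=1) - gt) / gt).max() < 0.02
        interior = np.abs(mad[2:-2] - gt[2:-2, None]) / gt[2:-2, None]
        assert interior.max() < 0.02

    def test_mad_scale_homogeneity(self, arched_mesh):
        grid = parameterize_mesh(arched_mesh, (32, 8))
        mad = mad_field(grid, medial_axis(grid))
        scaled = GridSurface(grid.points * 2.5)
        mad2 = mad_field(scaled, medial_axis(scaled))
        assert np.allclose(mad2, 2.5 * mad, rtol=1e-12)


class TestFeatureField:
    def test_subject_equals_template(self, arched_mesh):
        grid = parameterize_mesh(arched_mesh, (32, 8))
        ff = feature_field(grid, grid)
        assert np.abs(ff.logs3).max() < 1e-9
        assert np.abs(ff.detj - 1.0).max() < 1e-9
        assert np.allclose(ff.mad, mad_field(grid, medial_axis(grid)))
        assert ff.madmtbm().shape == (32, 8, 4)

    def test_uniform_scaling(self, arched_mesh):
        grid = parameterize_mesh(arched_mesh, (32, 8))
        scaled = GridSurface(grid.points * 2.0)
        ff = feature_field(scaled, grid)
        assert np.abs(ff.detj - 4.0).max() < 1e-6
        assert np.abs(ff.logs3[..., 0] - np.log(2)).max() < 1e-6
        assert np.abs(ff.logs3[..., 1]).max() < 1e-6
        assert np.abs(ff.logs3[..., 2] - np.log(2)).max() < 1e-6
        base = feature_field(grid, grid)
        assert np.allclose(ff.mad, 2.0 * base.mad, rtol=1e-9)

    def test_rigid_invariance(self, arched_mesh):
        template = parameterize_mesh(arched_mesh, (32, 8))
        cfg = CohortConfig(noise_sd=0.2, scale_jitter_sd=0.0,
                           rigid_rot_deg=0.0, rigid_trans_mm=0.0)
        subj = parameterize_mesh(sample_subject(cfg, "A", 9), (32, 8))
        ff = feature_field(subj, template)
        moved = GridSurface(subj.points @ _rot3(35, (1, 2, 0.5)).T
                            + np.array([4.0, -1.0, 2.0]))
        ff2 = feature_field(moved, template)
        assert np.abs(ff.logs3 - ff2.logs3).max() < 1e-6
        assert np.abs(ff.detj - ff2.detj).max() < 1e-6
        assert np.abs(ff.mad - ff2.mad).max() < 1e-6

    def test_radius_effect_shows_in_mad_ratio(self):
        base = CohortConfig(noise_sd=0.0, scale_jitter_sd=0.0,
                            rigid_rot_deg=0.0, rigid_trans_mm=0.0)
        eff = CohortConfig(effect_delta=0.2, effect_window=(0.3, 0.5),
                           noise_sd=0.0, scale_jitter_sd=0.0,
                           rigid_rot_deg=0.0, rigid_trans_mm=0.0)
        ga = parameterize_mesh(sample_subject(base, "A", 1), (64, 16))
        gb = parameterize_mesh(sample_subject(eff, "B", 1), (64, 16))
        ffa = feature_field(ga, ga)
        ffb = feature_field(gb, ga)
        ratio = ffb.mad / ffa.mad
        rows = window_rows(ga, (0.32, 0.48))
        outside = window_rows(ga, (0.6, 0.95))
        assert np.abs(ratio[rows].mean() - 1.2) < 0.02
        assert np.abs(ratio[outside] - 1.0).max() < 0.02

    def test_folded_correspondence_rejected(self, arched_mesh):
        grid = parameterize_mesh(arched_mesh, (32, 8))
        bad = grid.points.copy()
        bad[10, 3] = bad[10, 4]  # collapse a cell
        with pytest.raises(GeometryError):
            feature_field(GridSurface(bad), grid)
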
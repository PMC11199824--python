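"""Generator tests: medial curves, radius profiles, tubes, cohorts."""

import numpy as np
import pytest

from ccmorph import (
    CohortConfig,
    RadiusProfile,
    apply_group_effect,
    apply_shear_effect,
    default_radius_profile,
    derive_seed,
    generate_cohort,
    make_medial_curve,
    make_tube_surface,
    sample_subject,
)
from ccmorph.mesh import GeometryError
from ccmorph.synthetic import ConfigError, _smooth_noise_field


class TestMedialCurve:
    def test_zero_arch_is_straight_segment(self):
        c = make_medial_curve(10, 0.0, 100.0)
        assert np.allclose(c.points[:, 1:], 0.0)
        assert np.isclose(c.points[-1, 0] - c.points[0, 0], 100.0)
        assert np.isclose(c.arc_length(), 100.0, rtol=1e-6)

    def test_apex_height_matches_request(self):
        # odd point count: the symmetric arc's midpoint is the apex sample
        c = make_medial_curve(201, 20.0, 80.0)
        apex = c.points[:, 2].max()
        assert abs(apex - 20.0) < 1e-6
        # endpoints are the x extremes
        assert c.points[0, 0] == c.points[:, 0].min()
        assert c.points[-1, 0] == c.points[:, 0].max()

    @pytest.mark.parametrize("arch,length", [(0.0, 50.0), (20.0, 80.0), (30.0, 70.0)])
    def test_arclength_resampling_is_near_uniform(self, arch, length):
        c = make_medial_curve(64, arch, length)
        seg = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
        assert seg.max() / seg.min() < 1.1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigError):
            make_medial_curve(10, 10.0, -1.0)
        with pytest.raises(ConfigError):
            make_medial_curve(4, 10.0, 50.0)


class TestRadiusProfile:
    def test_group_effect_window_and_identity(self):
        prof = default_radius_profile()
        same = apply_group_effect(prof, (0.3, 0.5), 0.0)
        assert np.allclose(same.values, prof.values)

        boosted = apply_group_effect(prof, (0.3, 0.5), 0.2)
        ratio = boosted.values / prof.values
        t = prof.t_samples
        inside = (t >= 0.3) & (t <= 0.5)
        assert np.allclose(ratio[inside], 1.2)
        far = (t < 0.25) | (t > 0.55)
        assert np.allclose(ratio[far], 1.0)
        # value at t=0.9 unchanged
        th = prof.theta_samples
        assert np.allclose(boosted(0.9, th), prof(0.9, th))

    def test_taper_is_monotone_across_edges(self):
        prof = default_radius_profile(n_t=256)
        boosted = apply_group_effect(prof, (0.3, 0.5), 0.2, taper=0.05)
        ratio = boosted.values[:, 0] / prof.values[:, 0]
        t = prof.t_samples
        lo = (t >= 0.25) & (t <= 0.3)
        hi = (t >= 0.5) & (t <= 0.55)
        assert np.all(np.diff(ratio[lo]) >= -1e-12)
        assert np.all(np.diff(ratio[hi]) <= 1e-12)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ConfigError):
            apply_group_effect(default_radius_profile(), (0.3, 0.5), -1.0)

    def test_shear_twist_leaves_circular_profiles_unchanged(self):
        circ = default_radius_profile(ellipticity=0.0)
        twisted = apply_shear_effect(circ, (0.3, 0.5), 0.4)
        assert np.allclose(twisted.values, circ.values, atol=1e-9)

    def test_shear_twist_rotates_elliptic_sections_inside_window_only(self):
        prof = default_radius_profile(ellipticity=0.15)
        twisted = apply_shear_effect(prof, (0.3, 0.5), 0.4)
        t = prof.t_samples
        inside = (t > 0.33) & (t < 0.47)
        outside = (t < 0.29) | (t > 0.51)
        assert np.allclose(twisted.values[outside], prof.values[outside])
        assert np.abs(twisted.values[inside] - prof.values[inside]).max() > 0.01
        # the twist permutes radii around the ring: row min/max preserved
        assert np.allclose(sorted(twisted.values[40]), sorted(prof.values[40]),
                           atol=0.02)

    def test_profile_validation(self):
        with pytest.raises(ConfigError):
            RadiusProfile(np.linspace(0, 1, 4), np.arange(4) * np.pi / 2,
                          np.array([[1, 1, 1, 1], [1, 1, 1, 1],
                                    [1, 5, 1, 1], [1, 1, 1, 1]], float))


class TestTubeSurface:
    def test_cylinder_vertices_on_radius(self, straight_cylinder):
        d = np.linalg.norm(straight_cylinder.vertices[:, 1:], axis=1)
        assert np.allclose(d, 5.0, atol=1e-9)

    def test_cylinder_topology(self, straight_cylinder):
        assert len(straight_cylinder.boundary_loops()) == 2
        assert straight_cylinder.euler_characteristic() == 0

    def test_arched_tube_topology_and_quality(self, arched_mesh):
        arched_mesh.validate_cylinder()
        assert np.all(arched_mesh.face_areas() > 0)
        # no duplicated vertices
        v = np.round(arched_mesh.vertices / 1e-9).astype(np.int64)
        assert len(np.unique(v, axis=0)) == len(v)

    def test_outward_orientation(self, straight_cylinder):
        m = straight_cylinder
        f = m.faces
        nrm = np.cross(m.vertices[f[:, 1]] - m.vertices[f[:, 0]],
                       m.vertices[f[:, 2]] - m.vertices[f[:, 0]])
        centres = m.vertices[f].mean(axis=1)
        radial = centres.copy()
        radial[:, 0] = 0.0
        assert np.all((nrm * radial).sum(axis=1) > 0)

    def test_self_intersecting_sweep_rejected(self):
        curve = make_medial_curve(64, 20.0, 40.0)  # apex curvature radius 10 mm
        prof = RadiusProfile(np.linspace(0, 1, 8), np.arange(8) * np.pi / 4,
                             np.full((8, 8), 12.0))
        with pytest.raises(GeometryError, match="t="):
            make_tube_surface(curve, prof, (32, 8))


class TestSubjectSampling:
    def test_noise_free_subject_equals_group_template(self):
        cfg = CohortConfig(noise_sd=0.0, scale_jitter_sd=0.0,
                           rigid_rot_deg=0.0, rigid_trans_mm=0.0)
        subj = sample_subject(cfg, "B", 123)
        template = make_tube_surface(cfg.base_curve(), cfg.group_profile("B"),
                                     cfg.mesh_dims)
        expected = template.vertices.astype(np.float32).astype(np.float64)
        assert np.array_equal(subj.vertices, expected)
        assert np.array_equal(subj.faces, template.faces)

    def test_same_seed_is_bitwise_identical(self):
        cfg = CohortConfig()
        a = sample_subject(cfg, "A", 77)
        b = sample_subject(cfg, "A", 77)
        assert np.array_equal(a.vertices, b.vertices)

    def test_smooth_noise_marginal_sd_is_exact(self):
        rng = np.random.default_rng(0)
        draws = np.stack([_smooth_noise_field(rng, (64, 16), 0.5)
                          for _ in range(400)])
        sd = draws.std(axis=0)
        assert sd.min() > 0.4 and sd.max() < 0.6
        # smoothness: neighbouring samples strongly correlated
        corr = np.corrcoef(draws[:, 30, 7], draws[:, 31, 7])[0, 1]
        assert corr > 0.9

    def test_per_vertex_radial_sd_matches_nominal(self):
        cfg = CohortConfig(noise_sd=0.5, scale_jitter_sd=0.0,
                           rigid_rot_deg=0.0, rigid_trans_mm=0.0,
                           mesh_dims=(32, 12))
        curve = cfg.base_curve()
        t = np.linspace(0, 1, 32)
        axis = np.column_stack([np.interp(t, curve.t, curve.points[:, k])
                                for k in range(3)])
        radii = []
        for k in range(30):
            m = sample_subject(cfg, "A", 1000 + k)
            v = m.vertices.reshape(32, 12, 3)
            radii.append(np.linalg.norm(v - axis[:, None, :], axis=2))
        sd = np.stack(radii).std(axis=0)
        assert 0.3 < np.median(sd) < 0.7


class TestCohortGeneration:
    def test_cohort_counts_and_determinism(self, tmp_path):
        cfg = CohortConfig(n_per_group=3, mesh_dims=(16, 8), seed=5)
        man1 = generate_cohort(cfg, tmp_path / "run1")
        assert len(man1.table) == 6
        assert sorted(man1.table["group"].unique()) == ["A", "B"]
        assert all(p.exists() for p in man1.paths())
        assert man1.table["subject_id"].is_unique

        man2 = generate_cohort(cfg, tmp_path / "run2")
        for p1, p2 in zip(man1.paths(), man2.paths()):
            assert p1.read_bytes() == p2.read_bytes()
        cols = ["subject_id", "group", "seed", "effect_delta"]
        assert man1.table[cols].equals(man2.table[cols])

    def test_seed_splitting_is_stable_and_bounded(self):
        s1 = derive_seed(42, "subject", "A001")
        assert s1 == derive_seed(42, "subject", "A001")
        assert s1 != derive_seed(42, "subject", "A002")
        assert 0 <= s1 < 2**31
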
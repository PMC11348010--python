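import numpy as np
import pytest

from capgen import headmodel as hm
from capgen.errors import InvalidFiducialError, InvalidParameterError


class TestSyntheticHead:
    def test_sphere_circumference(self, sphere_head):
        hc = hm.measure_circumference(sphere_head)
        assert abs(hc - 565.0) / 565.0 < 0.005

    def test_sphere_cross_sections_are_circles(self, sphere_head, sphere_radius):
        v = sphere_head.mesh.vertices
        upper = v[v[:, 2] > 1.0]
        r_xy = np.sqrt(upper[:, 0] ** 2 + upper[:, 1] ** 2 + upper[:, 2] ** 2)
        assert np.allclose(r_xy, sphere_radius, rtol=1e-9)

    def test_vertex_count_increases_with_refinement(self):
        counts = [len(hm.generate_synthetic_head(56, (1, 1, 1), refinement=k)
                      .mesh.vertices) for k in (2, 3, 4)]
        assert counts[0] < counts[1] < counts[2]

    def test_fiducials_on_measuring_plane(self):
        for k in (2, 3, 4):
            head = hm.generate_synthetic_head(56, (1, 1, 1), refinement=k)
            for name in hm.FIDUCIAL_NAMES:
                assert head.fiducial_point(name)[2] == pytest.approx(0.0, abs=1e-9)

    def test_axis_ratio_anisotropy(self):
        # [DERIVED] analytic ellipsoid: y semi-axis 1.3x the x semi-axis
        head = hm.generate_synthetic_head(56, (1.0, 1.3, 1.0), refinement=3)
        d_nziz = np.linalg.norm(head.fiducial_point("Nz") - head.fiducial_point("Iz"))
        d_lr = np.linalg.norm(head.fiducial_point("LPA") - head.fiducial_point("RPA"))
        assert d_nziz / d_lr == pytest.approx(1.3, rel=0.01)

    @pytest.mark.parametrize("ratios", [(0, 1, 1), (1, -2, 1)])
    def test_invalid_ratios(self, ratios):
        with pytest.raises(InvalidParameterError):
            hm.generate_synthetic_head(56, ratios)

    def test_invalid_circumference_and_refinement(self):
        with pytest.raises(InvalidParameterError):
            hm.generate_synthetic_head(-1, (1, 1, 1))
        with pytest.raises(InvalidParameterError):
            hm.generate_synthetic_head(56, (1, 1, 1), refinement=1)


class TestLandmarks:
    def test_cz_at_pole(self, sphere_landmarks, sphere_radius):
        cz = sphere_landmarks.point("Cz")
        assert np.linalg.norm(cz - [0, 0, sphere_radius]) < 0.02 * sphere_radius

    def test_midline_10pct_at_18_degrees(self, sphere_landmarks):
        # [DERIVED] closed form: 10% of the Nz->Iz arc = 18 deg polar angle
        fpz = sphere_landmarks.point("Fpz")
        ang = np.degrees(np.arctan2(fpz[2], fpz[1]))
        assert ang == pytest.approx(18.0, abs=0.35)
        assert abs(fpz[0]) < 1e-6  # in the X=0 plane

    def test_cz_arc_equidistance(self, sphere_head, sphere_landmarks):
        lm = sphere_landmarks
        mesh = sphere_head.mesh
        nz, iz, cz = lm.point("Nz"), lm.point("Iz"), lm.point("Cz")
        a1 = hm.arc_length(mesh, nz, cz, (nz, iz, cz), via=cz)
        a2 = hm.arc_length(mesh, cz, iz, (nz, iz, cz), via=cz)
        assert abs(a1 - a2) < 0.5  # mm, solver tolerance on a 280 mm arc

    def test_scale_equivariance(self, sphere_head, sphere_landmarks):
        scaled = hm.HeadMesh(sphere_head.mesh.scaled(1.7), dict(sphere_head.fiducials))
        lm2 = hm.compute_10_5_landmarks(scaled)
        for label in ("Cz", "Fpz", "C3", "Oz", "T8", "Fp1"):
            assert np.allclose(lm2.point(label), sphere_landmarks.point(label) * 1.7,
                               atol=0.05)

    def test_sphere_closed_form_within_1pct(self, sphere_head, sphere_landmarks,
                                            sphere_radius):
        # midline labels at 5% arc increments vs exact spherical positions
        total = np.pi * sphere_radius
        for k, label in enumerate(hm.MIDLINE_LABELS):
            f = 0.05 * k
            ang = np.pi / 2 - f * np.pi     # polar angle from +Y toward -Y over top
            expect = sphere_radius * np.array([0.0, np.sin(ang), np.cos(ang)])
            err = np.linalg.norm(sphere_landmarks.point(label) - expect)
            assert err < 0.01 * total, f"{label}: {err:.2f} mm"

    def test_arc_additivity(self, sphere_head, sphere_landmarks):
        mesh = sphere_head.mesh
        lm = sphere_landmarks
        nz, iz, cz = lm.point("Nz"), lm.point("Iz"), lm.point("Cz")
        whole = hm.arc_length(mesh, nz, iz, (nz, iz, cz), via=cz)
        parts = (hm.arc_length(mesh, nz, cz, (nz, iz, cz), via=cz)
                 + hm.arc_length(mesh, cz, iz, (nz, iz, cz), via=cz))
        assert parts == pytest.approx(whole, rel=1e-6)

    def test_degenerate_fiducials_raise(self, sphere_head):
        bad = hm.HeadMesh(sphere_head.mesh,
                          {k: sphere_head.fiducials["Nz"] for k in hm.FIDUCIAL_NAMES})
        with pytest.raises(InvalidFiducialError):
            hm.compute_10_5_landmarks(bad)

    def test_full_grid_size(self, sphere_landmarks):
        assert len(sphere_landmarks.positions) > 150


class TestScaleHead:
    def test_explicit_factor(self, sphere_head, sphere_landmarks):
        hc0 = hm.measure_circumference(sphere_head)
        scaled, lm2 = hm.scale_head(sphere_head, sphere_landmarks, 58.0)
        f = 580.0 / hc0
        assert np.allclose(scaled.mesh.vertices, sphere_head.mesh.vertices * f)
        assert np.allclose(lm2.point("Cz"), sphere_landmarks.point("Cz") * f)

    def test_identity(self, sphere_head, sphere_landmarks):
        hc0 = hm.measure_circumference(sphere_head)
        scaled, _ = hm.scale_head(sphere_head, sphere_landmarks, hc0 / 10.0)
        assert np.allclose(scaled.mesh.vertices, sphere_head.mesh.vertices)

    def test_remeasured_circumference(self, sphere_head, sphere_landmarks):
        scaled, _ = hm.scale_head(sphere_head, sphere_landmarks, 58.0)
        assert hm.measure_circumference(scaled) == pytest.approx(580.0, rel=0.005)

    def test_idempotence(self, sphere_head, sphere_landmarks):
        s1, lm1 = hm.scale_head(sphere_head, sphere_landmarks, 58.0)
        s2, _ = hm.scale_head(s1, lm1, 58.0)
        assert np.allclose(s2.mesh.vertices, s1.mesh.vertices, atol=1e-9)

    def test_invalid_target(self, sphere_head):
        with pytest.raises(InvalidParameterError):
            hm.scale_head(sphere_head, None, -3.0)


class TestHeadIO:
    def test_stl_and_fiducial_sidecar_roundtrip(self, tmp_path, sphere_head):
        from capgen import mesh as mz

        mz.write_stl(sphere_head.mesh, tmp_path / "h.stl")
        hm.write_fiducials_json(sphere_head, tmp_path / "h.json")
        head2 = hm.load_head(tmp_path / "h.stl", tmp_path / "h.json")
        for name in hm.FIDUCIAL_NAMES:
            assert np.allclose(head2.fiducial_point(name),
                               sphere_head.fiducial_point(name), atol=1e-4)
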
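import numpy as np
import pytest

from capgen import mesh as mz
from capgen.errors import FormatError, GeometryError
from capgen.mesh import TriMesh


def unit_cube() -> TriMesh:
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                  [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
                  [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]])
    return TriMesh(v, f)


class TestBasics:
    def test_cube_volume_and_area(self):
        m = unit_cube()
        assert m.volume == pytest.approx(1.0)
        assert m.area == pytest.approx(6.0)
        assert m.is_watertight()

    def test_open_mesh_not_watertight(self):
        m = unit_cube()
        assert not TriMesh(m.vertices, m.faces[:-1]).is_watertight()

    def test_boundary_loop(self):
        m = unit_cube()
        m2 = TriMesh(m.vertices, m.faces[2:])  # remove bottom
        loops = m2.boundary_loops()
        assert len(loops) == 1
        assert len(loops[0]) == 4

    def test_ray_parity_through_cube(self):
        m = unit_cube()
        hits = m.ray_hits([0.31, 0.47, -1.0], [0, 0, 1.0])
        assert len(hits) == 2
        assert hits[0] == pytest.approx(1.0)
        assert hits[1] == pytest.approx(2.0)


class TestSTL:
    @pytest.mark.parametrize("mode", ["binary", "ascii"])
    def test_roundtrip(self, tmp_path, mode):
        m = unit_cube().scaled(10.0)
        p = tmp_path / f"cube_{mode}.stl"
        mz.write_stl(m, p, mode=mode)
        m2 = mz.read_stl(p)
        assert len(m2.faces) == len(m.faces)
        assert m2.volume == pytest.approx(1000.0, rel=1e-6)

    def test_binary_size_formula(self, tmp_path):
        m = unit_cube()
        p = tmp_path / "c.stl"
        mz.write_stl(m, p, mode="binary")
        assert p.stat().st_size == 84 + 50 * len(m.faces)

    def test_bad_mode(self, tmp_path):
        with pytest.raises(FormatError):
            mz.write_stl(unit_cube(), tmp_path / "x.stl", mode="nope")


class TestOFF:
    def test_roundtrip(self, tmp_path):
        m = unit_cube()
        p = tmp_path / "cube.off"
        mz.write_off(m, p)
        m2 = mz.read_off(p)
        assert np.allclose(m2.vertices, m.vertices)
        assert np.array_equal(m2.faces, m.faces)


class TestEmbedPoint:
    def test_interior_split_counts(self):
        m = unit_cube()
        centroid = m.triangles[0].mean(axis=0)
        m2, vid = mz.embed_point(m, centroid)
        assert len(m2.vertices) == len(m.vertices) + 1
        assert len(m2.faces) == len(m.faces) + 2
        assert np.allclose(m2.vertices[vid], centroid)

    def test_vertex_snap_is_identity(self):
        m = unit_cube()
        m2, vid = mz.embed_point(m, m.vertices[3])
        assert vid == 3
        assert len(m2.vertices) == len(m.vertices)
        assert len(m2.faces) == len(m.faces)

    def test_edge_split_counts(self):
        m = unit_cube()
        mid = 0.5 * (m.vertices[4] + m.vertices[5])  # top-face edge
        m2, vid = mz.embed_point(m, mid)
        assert len(m2.vertices) == len(m.vertices) + 1
        assert len(m2.faces) == len(m.faces) + 2

    def test_far_point_raises(self):
        with pytest.raises(GeometryError):
            mz.embed_point(unit_cube(), [5.0, 5.0, 5.0])

    def test_area_conserved_100_random_points(self, sphere_head):
        m = sphere_head.mesh
        a0 = m.area
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.normal(size=3)
            p = p / np.linalg.norm(p)
            p[2] = abs(p[2])
            p = p * np.linalg.norm(sphere_head.fiducial_point("Nz"))
            surf = m.closest_point(p)[0][0]
            m, _ = mz.embed_point(m, surf)
        assert abs(m.area - a0) / a0 < 1e-9


class TestSlicing:
    def test_great_circle_arc(self, sphere_head, sphere_radius):
        from capgen.headmodel import arc_length

        nz = sphere_head.fiducial_point("Nz")
        iz = sphere_head.fiducial_point("Iz")
        top = np.array([0, 0, sphere_radius])
        L = arc_length(sphere_head.mesh, nz, iz, (nz, iz, top), via=top)
        assert L == pytest.approx(np.pi * sphere_radius, rel=5e-3)

    def test_zero_length_arc(self, sphere_head, sphere_radius):
        from capgen.headmodel import arc_length

        nz = sphere_head.fiducial_point("Nz")
        iz = sphere_head.fiducial_point("Iz")
        top = np.array([0, 0, sphere_radius])
        assert arc_length(sphere_head.mesh, nz, nz, (nz, iz, top)) == 0.0

    def test_arc_error_decreases_with_refinement(self):
        from capgen.headmodel import arc_length, generate_synthetic_head

        errs = []
        for k in (2, 3, 4):
            head = generate_synthetic_head(56.5, (1, 1, 1), refinement=k)
            r = np.linalg.norm(head.fiducial_point("Nz"))
            nz, iz = head.fiducial_point("Nz"), head.fiducial_point("Iz")
            L = arc_length(head.mesh, nz, iz, (nz, iz, [0, 0, r]), via=[0, 0, r])
            errs.append(abs(L - np.pi * r))
        assert errs[0] > errs[1] > errs[2]

    def test_plane_misses_mesh(self, sphere_head):
        with pytest.raises(GeometryError):
            mz.slice_plane(sphere_head.mesh, np.array([0, 0, 500.0]),
                           np.array([0, 0, 1.0]))


class TestSplitWithPlane:
    def test_area_conservation(self, sphere_head):
        m = sphere_head.mesh
        (pos, _), (neg, _) = mz.split_with_plane(m, np.array([0, 0, 30.0]),
                                                 np.array([0, 0, 1.0]))
        assert pos.area + neg.area == pytest.approx(m.area, rel=1e-9)

    def test_provenance(self, sphere_head):
        m = sphere_head.mesh
        (pos, prov), _ = mz.split_with_plane(m, np.array([0, 0, 30.0]),
                                             np.array([0, 0, 1.0]))
        old = prov >= 0
        assert np.allclose(pos.vertices[old], m.vertices[prov[old]])
        assert (~old).sum() > 0  # some cut vertices exist
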
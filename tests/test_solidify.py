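import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from capgen import mesh as mz
from capgen import solidify as so
from capgen.errors import (GeometryError, InvalidParameterError, LibraryError,
                           PlacementError)
from capgen.panel2d import GrommetPlacement, PanelDesign, hex_fill


def voxel_volume(mesh, n=120, seed=11):
    """Independent ray-parity volume oracle.

    One ray per cell, jittered uniformly inside the cell (fixed seed):
    unbiased Monte Carlo column sampling, error ~ 1/sqrt(N) of the
    boundary-cell population.
    """
    rng = np.random.default_rng(seed)
    x0, x1 = mesh.vertices[:, 0].min(), mesh.vertices[:, 0].max()
    y0, y1 = mesh.vertices[:, 1].min(), mesh.vertices[:, 1].max()
    dx, dy = (x1 - x0) / n, (y1 - y0) / n
    total = 0.0
    for i in range(n):
        for j in range(n):
            x = x0 + (i + rng.uniform()) * dx
            y = y0 + (j + rng.uniform()) * dy
            h = mesh.ray_hits([x, y, -100.0], [0, 0, 1.0])
            for k in range(0, len(h) // 2 * 2, 2):
                total += (h[k + 1] - h[k]) * dx * dy
    return total


@pytest.fixture()
def small_panel():
    sq = Polygon([(0, 0), (40, 0), (40, 40), (0, 40)])
    return PanelDesign("left", sq, lattice=hex_fill(sq))


class TestExtrude:
    def test_single_beam_prism_volume(self):
        beam = LineString([(0, 0), (50, 0)]).buffer(0.425, cap_style="flat")
        m = so.stack_solid([(beam, 0.0, 0.9)])
        assert m.volume == pytest.approx(50 * 0.85 * 0.9, rel=1e-6)
        assert m.is_watertight()

    def test_z_extent_equals_thickness(self, small_panel):
        sp = so.extrude_panel(small_panel, 0.9)
        z = sp.mesh.vertices[:, 2]
        assert z.min() == 0.0
        assert z.max() == 0.9

    def test_lattice_volume_vs_voxel_oracle(self, small_panel):
        sp = so.extrude_panel(small_panel)
        vv = voxel_volume(sp.mesh)
        assert abs(vv - sp.volume) / sp.volume < 0.02

    def test_watertight_and_positive(self, small_panel):
        sp = so.extrude_panel(small_panel)
        assert sp.mesh.is_watertight()
        assert sp.volume > 0

    def test_invalid_thickness(self, small_panel):
        with pytest.raises(InvalidParameterError):
            so.extrude_panel(small_panel, -1.0)


class TestDefaultGrommet:
    def test_volume_closed_form(self):
        g = so.make_default_grommet(11, 16, 5)
        analytic = np.pi * (8.0 ** 2 - 5.5 ** 2) * 5.0
        assert abs(g.volume - analytic) / analytic < 0.02
        assert g.is_watertight()

    def test_origin_at_base_center(self):
        g = so.make_default_grommet(11, 16, 5)
        assert g.vertices[:, 2].min() == 0.0
        c = g.vertices[:, :2]
        assert np.allclose(c.mean(axis=0), [0, 0], atol=0.1)

    def test_invalid_radii(self):
        with pytest.raises(InvalidParameterError):
            so.make_default_grommet(16, 11, 5)
        with pytest.raises(InvalidParameterError):
            so.make_default_grommet(5, 10, -1)

    def test_hole_through_after_union_with_plate(self, grommet_library_dir,
                                                 small_panel):
        lib = so.GrommetLibrary(grommet_library_dir)
        sp = so.extrude_panel(small_panel)
        sp2 = so.place_grommets(
            sp, [GrommetPlacement(np.array([20.0, 20.0]), 0.0, "#STD", "optode:0")],
            lib)
        assert sp2.mesh.is_watertight()
        # ray through the grommet's inner hole passes clean through
        hits = sp2.mesh.ray_hits([20.013, 20.007, -5.0], [0, 0, 1.0])
        assert len(hits) == 0
        # ray through the ring wall enters and exits the grommet body
        hits2 = sp2.mesh.ray_hits([26.763, 20.017, -5.0], [0, 0, 1.0])
        assert len(hits2) >= 2


class TestPlaceGrommets:
    def test_no_grommets_is_identity(self, small_panel, grommet_library_dir):
        sp = so.extrude_panel(small_panel)
        sp2 = so.place_grommets(sp, [], so.GrommetLibrary(grommet_library_dir))
        assert sp2 is sp

    def test_manifest_lists_both(self, small_panel, grommet_library_dir):
        lib = so.GrommetLibrary(grommet_library_dir)
        sp = so.extrude_panel(small_panel)
        pl = [GrommetPlacement(np.array([12.0, 12.0]), 0.0, "#STD", "optode:0"),
              GrommetPlacement(np.array([28.0, 28.0]), 45.0, "#STD", "optode:1")]
        sp2 = so.place_grommets(sp, pl, lib)
        gs = sp2.manifest["grommets"]
        assert len(gs) == 2
        assert gs[0]["position"] == [12.0, 12.0]
        assert gs[1]["rotation"] == 45.0

    def test_volume_vs_voxel_oracle(self, small_panel, grommet_library_dir):
        lib = so.GrommetLibrary(grommet_library_dir)
        sp = so.extrude_panel(small_panel)
        sp2 = so.place_grommets(
            sp, [GrommetPlacement(np.array([20.0, 20.0]), 0.0, "#STD", "optode:0")],
            lib)
        vv = voxel_volume(sp2.mesh, n=140)
        assert abs(vv - sp2.volume) / sp2.volume < 0.02

    def test_unknown_id_names_the_grommet(self, small_panel, grommet_library_dir):
        lib = so.GrommetLibrary(grommet_library_dir)
        sp = so.extrude_panel(small_panel)
        with pytest.raises(LibraryError, match="#NOPE"):
            so.place_grommets(
                sp, [GrommetPlacement(np.array([20.0, 20.0]), 0.0, "#NOPE", "x")],
                lib)

    def test_manifest_idempotent(self, small_panel, grommet_library_dir):
        lib = so.GrommetLibrary(grommet_library_dir)
        pl = [GrommetPlacement(np.array([20.0, 20.0]), 30.0, "#STD", "optode:0")]
        m1 = so.place_grommets(so.extrude_panel(small_panel), pl, lib).manifest
        m2 = so.place_grommets(so.extrude_panel(small_panel), pl, lib).manifest
        assert m1["grommets"] == m2["grommets"]


def _side_plate():
    plate = Polygon([(0, -60), (160, -60), (160, 40), (0, 40)])
    return PanelDesign("left", plate, lattice=hex_fill(plate))


class TestEarSlit:
    def test_center_15mm_up_from_ear_point(self):
        sp = so.extrude_panel(_side_plate())
        sp2 = so.add_ear_slit(sp, np.array([80.0, -30.0]), up_dir=[0, 1],
                              rear_dir=[1, 0])
        feat = sp2.manifest["features"][-1]
        center = np.array(feat["center"])
        ear = np.array(feat["ear_point"])
        up = np.array(feat["up"])
        assert float(np.dot(center - ear, up)) == pytest.approx(15.0, abs=1e-9)
        assert sp2.mesh.is_watertight()

    def test_panel_stays_connected(self):
        sp = so.extrude_panel(_side_plate())
        sp2 = so.add_ear_slit(sp, np.array([80.0, -30.0]), up_dir=[0, 1],
                              rear_dir=[1, 0])
        # ray through slit interior: no material
        c = sp2.manifest["features"][-1]["center"]
        assert len(sp2.mesh.ray_hits([c[0] + 0.013, c[1] + 0.007, -5], [0, 0, 1.0])) == 0

    def test_hole_area_matches_template(self):
        sp = so.extrude_panel(_side_plate())
        sp2 = so.add_ear_slit(sp, np.array([80.0, -30.0]), up_dir=[0, 1],
                              rear_dir=[1, 0], length=34.0, width=18.0)
        feat = sp2.manifest["features"][-1]
        # stadium area: rectangle + end caps
        expect = (34.0 - 18.0) * 18.0 + np.pi * 9.0 ** 2
        assert abs(feat["hole_area"] - expect) / expect < 0.02

    def test_severing_slit_raises(self):
        # a narrow bridge panel: the slit cuts it into two pieces
        bridge = Polygon([(0, 0), (100, 0), (100, 12), (0, 12)])
        d = PanelDesign("left", bridge, lattice=hex_fill(bridge))
        sp = so.extrude_panel(d)
        # no reinforcing ring: the slit alone must not sever the panel
        with pytest.raises(GeometryError):
            so.add_ear_slit(sp, np.array([50.0, -9.0]), up_dir=[0, 1],
                            rear_dir=[1, 0], length=40.0, width=20.0,
                            ring_width=0.0)


class TestStrapHolders:
    def test_two_holders_slot_open_watertight(self):
        sp = so.extrude_panel(_side_plate())
        sp2 = so.add_strap_holders(sp, [
            {"center": [30.0, -40.0], "axis": [1.0, 0.0], "name": "chin"},
            {"center": [130.0, -40.0], "axis": [1.0, 0.0], "name": "neck"},
        ])
        feats = [f for f in sp2.manifest["features"] if f["type"] == "strap_holder"]
        assert len(feats) == 2
        assert sp2.mesh.is_watertight()
        # slot stays open
        assert len(sp2.mesh.ray_hits([30.013, -40.007, -5], [0, 0, 1.0])) == 0

    def test_detached_holder_raises(self):
        sp = so.extrude_panel(_side_plate())
        with pytest.raises(PlacementError):
            so.add_strap_holders(sp, [{"center": [500.0, 500.0],
                                       "axis": [1.0, 0.0], "name": "x"}])


class TestMeshToLayers:
    def test_extrusion_is_exact(self):
        g = so.make_default_grommet(11, 16, 5)
        layers = so.mesh_to_layers(g)
        assert len(layers) == 1
        geom, z0, z1 = layers[0]
        assert (z0, z1) == (0.0, 5.0)
        analytic = np.pi * (8.0 ** 2 - 5.5 ** 2)
        assert abs(geom.area - analytic) / analytic < 0.02


class TestSTLOutput:
    def test_roundtrip_and_size(self, tmp_path, small_panel):
        sp = so.extrude_panel(small_panel)
        p = tmp_path / "p.stl"
        so.write_stl(sp, p)
        assert p.stat().st_size == 84 + 50 * len(sp.mesh.faces)
        m2 = mz.read_stl(p)
        assert len(m2.faces) == len(sp.mesh.faces)
        assert m2.volume == pytest.approx(sp.volume, abs=1e-3)

    def test_ascii_mode(self, tmp_path, small_panel):
        sp = so.extrude_panel(small_panel)
        p = tmp_path / "p_ascii.stl"
        so.write_stl(sp, p, mode="ascii")
        m2 = mz.read_stl(p)
        assert len(m2.faces) == len(sp.mesh.faces)
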
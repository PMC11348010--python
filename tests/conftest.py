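"""Shared fixtures: synthetic heads, analytic panels, and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from capgen import headmodel as hm
from capgen import probe as pb
from capgen import surface_prep as sp
from capgen.fixtures import write_default_grommet_library
from capgen.mesh import TriMesh
from capgen.pipeline import CapConfig, generate_cap, resolve_head, resolve_probe
from capgen.surface_prep import PanelSurface


@pytest.fixture(scope="session")
def sphere_head():
    """Spherical head (all ratios 1), HC 56.5 cm, refinement 3."""
    return hm.generate_synthetic_head(56.5, (1.0, 1.0, 1.0), refinement=3)


@pytest.fixture(scope="session")
def sphere_landmarks(sphere_head):
    return hm.compute_10_5_landmarks(sphere_head)


@pytest.fixture(scope="session")
def sphere_radius(sphere_head):
    return float(np.linalg.norm(sphere_head.fiducial_point("Nz")))


def make_cylinder_strip(r=90.0, phi=1.2, h=60.0, nu=24, nv=12) -> TriMesh:
    """Developable strip of a cylinder: unrolls exactly to r*phi x h."""
    us = np.linspace(-phi / 2, phi / 2, nu)
    vs = np.linspace(0, h, nv)
    V = np.array([[r * np.sin(u), v, r * np.cos(u)] for v in vs for u in us])
    F = []
    for j in range(nv - 1):
        for i in range(nu - 1):
            a = j * nu + i
            F += [[a, a + 1, a + nu + 1], [a, a + nu + 1, a + nu]]
    return TriMesh(V, np.array(F))


def make_spherical_cap(r=90.0, theta=0.7, nlat=12, nlon=36) -> TriMesh:
    V = [[0.0, 0.0, r]]
    for j in range(1, nlat + 1):
        th = theta * j / nlat
        for i in range(nlon):
            ph = 2 * np.pi * i / nlon
            V.append([r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph),
                      r * np.cos(th)])
    F = []

    def vid(j, i):
        return 1 + (j - 1) * nlon + (i % nlon)

    for i in range(nlon):
        F.append([0, vid(1, i), vid(1, i + 1)])
    for j in range(1, nlat):
        for i in range(nlon):
            a, b = vid(j, i), vid(j, i + 1)
            c, d = vid(j + 1, i + 1), vid(j + 1, i)
            F += [[a, c, b], [a, d, c]]
    return TriMesh(np.array(V, dtype=float), np.array(F))


@pytest.fixture()
def cylinder_panel():
    m = make_cylinder_strip()
    return PanelSurface(m, np.arange(len(m.vertices)), "left")


@pytest.fixture()
def cap_panel():
    m = make_spherical_cap()
    return PanelSurface(m, np.arange(len(m.vertices)), "mid")


@pytest.fixture(scope="session")
def grommet_library_dir(tmp_path_factory):
    return write_default_grommet_library(tmp_path_factory.mktemp("grommets"))


@pytest.fixture(scope="session")
def pipeline_stage(tmp_path_factory):
    """Registered + embedded + cut default head (shared, pre-flattening)."""
    cfg = CapConfig()
    head = resolve_head("synthetic", cfg)
    landmarks = hm.compute_10_5_landmarks(head)
    head, landmarks = hm.scale_head(head, landmarks, cfg.hc_cm)
    probe = resolve_probe("default")
    reg = pb.register_probe(probe, head, landmarks)
    points = dict(landmarks.positions)
    points.update(sp.axial_cut_marker_points(head, cfg.axial_cut_offset))
    for i in range(len(probe.optodes)):
        points[f"optode:{i}"] = reg.positions[i]
    head_e, marker_ids = sp.embed_points(head, points)
    cut = sp.cut_panels(head_e, landmarks, marker_ids,
                        axial_offset=cfg.axial_cut_offset,
                        mid_fraction=cfg.mid_fraction)
    return {"cfg": cfg, "head": head, "head_e": head_e, "landmarks": landmarks,
            "probe": probe, "registration": reg, "markers": marker_ids, "cut": cut}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("cap_out")
    report = generate_cap(config=CapConfig(), out_dir=out)
    return {"report": report, "out": out}
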
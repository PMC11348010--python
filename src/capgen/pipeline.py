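"""End-to-end cap generation: head -> landmarks -> probe registration ->
panel cutting -> flattening -> 2D designs -> solids -> STL files + report.

A full run emits exactly four panel solids (left, right, mid-front,
mid-back), a JSON report with distortion metrics, the grommet manifest and
the tab pairing table, and is deterministic for fixed inputs and config.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import headmodel as hm
from . import mesh as mz
from . import panel2d as p2
from . import probe as pb
from . import solidify as so
from . import surface_prep as sp
from .errors import CapgenError, InvalidParameterError, LibraryError, PlacementError
from .fixtures import default_probe, write_default_grommet_library
from .flattening import FlatMesh, FlattenConfig, distortion_report, flatten_panel

PANEL_FILES = {"left": "panel_left.stl", "right": "panel_right.stl",
               "mid-front": "panel_mid_front.stl", "mid-back": "panel_mid_back.stl"}


@dataclass
class CapConfig:
    """Every geometric parameter of the pipeline, with printed defaults."""

    hc_cm: float = 56.0                 # target head circumference
    hex_edge: float = 10.0              # hexagon edge length, mm
    lattice_width: float = 0.85         # lattice beam width, mm
    tab_width: float = 2.0              # welding tab width, mm
    extrude: float = 0.9                # extrusion thickness, mm
    gravity_step: float = 0.1           # flattening gravity cap, mm/step
    z_tol: float = 0.1                  # flattening Z convergence, mm
    ear_slit_offset: float = 15.0       # slit center above LPA/RPA, mm
    ear_slit_slant_deg: float = 20.0
    ear_slit_length: float = 34.0
    ear_slit_width: float = 18.0
    axial_cut_offset: float = 15.0      # axial plane above Nz, mm
    mid_fraction: float = 3.0 / 7.0     # coronal-arc share of the mid panel
    mid_fraction_mode: str = "arc"      # "arc" (default) or "euclidean"
    tab_reach: float = 10.0             # seam-edge search distance, mm
    area_tol: float = 0.05              # flattening area conservation
    max_iters: int = 50000
    disp_tol: float = 1e-4              # flattening spring settle tolerance
    # synthetic head defaults
    axis_ratios: tuple = (1.0, 1.25, 0.9)
    refinement: int = 3
    skirt_depth: float = 25.0
    # paths
    grommet_library: str | None = None  # default: generated #STD library
    out_dir: str = "out"
    # scaling by Iz-Nz / LPA-RPA distances is noted as an alternative in the
    # source method but is not implemented here; only HC scaling is active.
    scale_mode: str = "HC"

    def validate(self) -> None:
        positive = ("hc_cm", "hex_edge", "lattice_width", "tab_width", "extrude",
                    "gravity_step", "z_tol", "ear_slit_offset", "axial_cut_offset",
                    "tab_reach", "area_tol", "disp_tol")
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"config field {name} must be > 0")
        if not 0 < self.mid_fraction < 1:
            raise InvalidParameterError("mid_fraction must be in (0, 1)")
        if self.scale_mode != "HC":
            raise InvalidParameterError(
                "only HC scaling is implemented (scale_mode='HC')")

    def flatten_config(self) -> FlattenConfig:
        return FlattenConfig(gravity_step=self.gravity_step, z_tol=self.z_tol,
                             disp_tol=self.disp_tol, max_iters=self.max_iters,
                             area_tol=self.area_tol)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axis_ratios"] = list(self.axis_ratios)
        return d

    @classmethod
    def from_yaml(cls, path) -> "CapConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "CapConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "axis_ratios" in data:
            data = dict(data)
            data["axis_ratios"] = tuple(data["axis_ratios"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# input resolution
# ---------------------------------------------------------------------------


def resolve_head(head_source, cfg: CapConfig) -> hm.HeadMesh:
    """head_source: "synthetic" | "synthetic:<HC>[:a,b,c]" | (mesh, fiducials)
    paths | an existing HeadMesh."""
    if isinstance(head_source, hm.HeadMesh):
        return head_source
    if isinstance(head_source, (tuple, list)) and len(head_source) == 2:
        return hm.load_head(head_source[0], head_source[1])
    if isinstance(head_source, str) and head_source.startswith("synthetic"):
        parts = head_source.split(":")
        hc = float(parts[1]) if len(parts) > 1 and parts[1] else cfg.hc_cm
        ratios = (tuple(float(x) for x in parts[2].split(","))
                  if len(parts) > 2 else cfg.axis_ratios)
        return hm.generate_synthetic_head(hc, ratios, cfg.refinement,
                                          skirt_depth=cfg.skirt_depth)
    raise InvalidParameterError(f"cannot interpret head source {head_source!r}")


def resolve_probe(probe_source) -> pb.ProbeDesign:
    if isinstance(probe_source, pb.ProbeDesign):
        return probe_source
    if probe_source in (None, "default"):
        return default_probe()
    return pb.read_probe_design(probe_source)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _stage(log, name):
    log.append({"stage": name, "t": time.strftime("%H:%M:%S")})


def _axial_frame(flat: FlatMesh, panel: sp.PanelSurface, cut_marker: str):
    """(flat cut point, up unit, rear unit) at the ear marker of a side panel."""
    vid = panel.markers[cut_marker]
    p = flat.xy[vid]
    # axial boundary tangent, oriented toward decreasing 3D Y (rear)
    ax = [v for v, lbl in panel.boundary_vertex_labels.items() if lbl == "axial"]
    ax = sorted(ax, key=lambda v: panel.mesh.vertices[v, 1])
    pts2 = flat.xy[ax]
    y3 = panel.mesh.vertices[ax, 1]
    # local tangent by least squares around the marker
    w = np.exp(-0.5 * ((y3 - panel.mesh.vertices[vid, 1]) / 30.0) ** 2)
    d2 = pts2 - np.average(pts2, axis=0, weights=w)
    cov = (d2 * w[:, None]).T @ d2
    tangent = np.linalg.svd(cov)[0][:, 0]
    # rear = direction of decreasing 3D y along the boundary
    corr = np.polyfit(y3, pts2 @ tangent, 1)[0]
    rear = -tangent if corr > 0 else tangent
    up = np.array([-rear[1], rear[0]])
    sag = [v for v, lbl in panel.boundary_vertex_labels.items()
           if lbl.startswith("sagittal")]
    target = flat.xy[sag].mean(axis=0) if sag else flat.xy.mean(axis=0)
    if np.dot(target - p, up) < 0:
        up = -up
    return p, up, rear


def _grommet_placements(probe: pb.ProbeDesign, flats: dict[str, FlatMesh],
                        panels: dict[str, sp.PanelSurface]) -> dict[str, list]:
    """Assign each optode to the panel holding its vertex; mid wins ties."""
    out = {role: [] for role in flats}
    for i, o in enumerate(probe.optodes):
        name = f"optode:{i}"
        role = None
        for r in ("mid", "left", "right"):
            if r in panels and name in panels[r].markers:
                role = r
                break
        if role is None:
            raise PlacementError(f"optode {i} not found in any panel")
        vid = panels[role].markers[name]
        out[role].append(p2.GrommetPlacement(
            flats[role].xy[vid].copy(), o.rotation, o.grommet_id, name))
    return out


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------


def generate_cap(head_source="synthetic", probe_source="default",
                 config: CapConfig | None = None, out_dir=None,
                 keep_intermediates: bool = False, stl_mode: str = "binary") -> dict:
    """Run the full pipeline; returns the report dict (also written to disk)."""
    cfg = config or CapConfig()
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    log: list[dict] = []
    t_start = time.time()

    _stage(log, "head")
    head = resolve_head(head_source, cfg)
    landmarks = hm.compute_10_5_landmarks(head)
    head, landmarks = hm.scale_head(head, landmarks, cfg.hc_cm)

    _stage(log, "probe")
    probe = resolve_probe(probe_source)
    report_v = pb.validate_probe(probe, landmarks)
    if not report_v["valid"]:
        raise CapgenError(f"stage probe: invalid probe: {report_v['violations']}")
    reg = pb.register_probe(probe, head, landmarks)

    _stage(log, "embed")
    points = dict(landmarks.positions)
    points.update(sp.axial_cut_marker_points(head, cfg.axial_cut_offset))
    for i in range(len(probe.optodes)):
        points[f"optode:{i}"] = reg.positions[i]
    head_e, marker_ids = sp.embed_points(head, points)

    _stage(log, "cut")
    cut = sp.cut_panels(head_e, landmarks, marker_ids,
                        axial_offset=cfg.axial_cut_offset,
                        mid_fraction=cfg.mid_fraction,
                        fraction_mode=cfg.mid_fraction_mode)
    panels = cut.panels

    _stage(log, "flatten")
    fcfg = cfg.flatten_config()
    flats = {role: flatten_panel(panel, fcfg) for role, panel in panels.items()}
    distortion = {role: distortion_report(flats[role], panels[role])
                  for role in flats}

    _stage(log, "designs")
    placements = _grommet_placements(probe, flats, panels)
    mid_front, mid_back = p2.build_mid_outlines(flats["mid"], panels["mid"],
                                                placements["mid"])
    designs = {"mid-front": mid_front, "mid-back": mid_back}
    ear_frames = {}
    for role in ("left", "right"):
        d = p2.build_side_outline(flats[role], panels[role])
        d.grommets = placements[role]
        designs[role] = d
        marker = "LPA_cut" if role == "left" else "RPA_cut"
        p, up, rear = _axial_frame(flats[role], panels[role], marker)
        fid = "LPA" if role == "left" else "RPA"
        h_cut = float(head_e.mesh.vertices[marker_ids[marker], 2]
                      - head.fiducial_point(fid)[2])
        flat_ear = p - h_cut * up
        ear_frames[role] = {"ear_point": flat_ear, "up": up, "rear": rear}
        d.meta["ear_frame"] = {k: v.tolist() for k, v in ear_frames[role].items()}

    for role, d in designs.items():
        d.lattice = p2.hex_fill(d.outline, cfg.hex_edge, cfg.lattice_width)

    _stage(log, "tabs")
    tab_reports = [
        p2.generate_weld_tabs(designs["left"], [mid_front, mid_back],
                              "sagittal-left", cfg.tab_width, cfg.tab_reach,
                              cfg.hex_edge),
        p2.generate_weld_tabs(designs["right"], [mid_front, mid_back],
                              "sagittal-right", cfg.tab_width, cfg.tab_reach,
                              cfg.hex_edge),
        p2.generate_weld_tabs(mid_front, mid_back, "midline",
                              cfg.tab_width, cfg.tab_reach, cfg.hex_edge),
    ]

    _stage(log, "solidify")
    if cfg.grommet_library:
        lib = so.GrommetLibrary(Path(cfg.grommet_library))
    else:
        lib = so.GrommetLibrary(write_default_grommet_library(out / "_grommet_library"))
    solids = {}
    for role, d in designs.items():
        try:
            solid = so.extrude_panel(d, cfg.extrude)
            solid = so.place_grommets(solid, d.grommets, lib, cfg.extrude)
            if role in ("left", "right"):
                ef = ear_frames[role]
                solid = so.add_ear_slit(solid, ef["ear_point"], ef["up"], ef["rear"],
                                        offset=cfg.ear_slit_offset,
                                        slant_deg=cfg.ear_slit_slant_deg,
                                        length=cfg.ear_slit_length,
                                        width=cfg.ear_slit_width)
                solid = so.add_strap_holders(solid, _holder_positions(d))
            solids[role] = solid
        except LibraryError as e:
            raise LibraryError(f"stage solidify ({role}): {e}") from e

    _stage(log, "write")
    out.mkdir(parents=True, exist_ok=True)
    stl_files = {}
    for role, solid in solids.items():
        path = out / PANEL_FILES[role]
        so.write_stl(solid, path, mode=stl_mode)
        so.write_manifest(solid, path.with_suffix(".manifest.json"))
        stl_files[role] = str(path)

    report = {
        "config": cfg.to_dict(),
        "panels": stl_files,
        "distortion": distortion,
        "registration": {"max_spring_error_mm": reg.max_spring_error,
                         "iterations": reg.iterations},
        "cut": {"x0_mm": cut.x0, "discarded_area_mm2": cut.discarded_area},
        "tabs": tab_reports,
        "grommets": {role: s.manifest["grommets"] for role, s in solids.items()},
        "features": {role: s.manifest.get("features", []) for role, s in solids.items()},
        "solids": {role: so.validate_solid(s.mesh) for role, s in solids.items()},
        "log": log,
        "runtime_s": time.time() - t_start,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    if keep_intermediates:
        inter = out / "intermediates"
        inter.mkdir(exist_ok=True)
        for role, flat in flats.items():
            mz.write_off(flat.mesh2d(), inter / f"flat_{role}.off")
        for role, d in designs.items():
            with open(inter / f"design_{role}.json", "w") as fh:
                json.dump(d.to_dict(), fh, default=_json_default)
    return report


def _holder_positions(design: p2.PanelDesign) -> list[dict]:
    """Chin (anterior) and neck (posterior) strap holders on the lower outline."""
    ef = design.meta.get("ear_frame")
    rear = np.asarray(ef["rear"]) if ef else np.array([1.0, 0.0])
    up = np.asarray(ef["up"]) if ef else np.array([0.0, 1.0])
    ear = np.asarray(ef["ear_point"]) if ef else np.array(design.outline.centroid.coords[0])
    return [
        {"name": "chin", "center": ear - 45.0 * rear + 2.0 * up, "axis": -rear},
        {"name": "neck", "center": ear + 45.0 * rear + 2.0 * up, "axis": rear},
    ]


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def verify_cap(report: dict | str, panels_dir=None,
               coupling_tol: float = 0.2, area_tol: float | None = None) -> dict:
    """Assert the invariant suite over a finished run; returns a summary."""
    if not isinstance(report, dict):
        with open(report) as fh:
            report = json.load(fh)
    area_tol = area_tol if area_tol is not None else report["config"]["area_tol"]
    checks = []

    def check(name, ok, detail=""):
        checks.append({"check": name, "pass": bool(ok), "detail": detail})

    for role, d in report["distortion"].items():
        check(f"area-ratio:{role}", abs(d["area_ratio"] - 1) <= area_tol,
              f"{d['area_ratio']:.4f}")
        check(f"max-z:{role}", d["max_z"] <= report["config"]["z_tol"] + 1e-9,
              f"{d['max_z']:.4f}")
        check(f"coupling:{role}", d["coupling_residual_max"] <= coupling_tol,
              f"{d['coupling_residual_max']:.4f}")
    # tab bijection: each pair id appears in >= 2 member panels
    for tr in report["tabs"]:
        for pair in tr["pairs"]:
            roles = {m["role"] for m in pair["members"]}
            check(f"tab-pair:{pair['pair_id']}", len(roles) >= 2, str(sorted(roles)))
    for role, s in report["solids"].items():
        check(f"watertight:{role}", s["watertight"])
        check(f"volume:{role}", s["positive_volume"], f"{s['volume']:.1f}")
    if panels_dir is not None:
        for role, fname in PANEL_FILES.items():
            path = Path(panels_dir) / fname
            if path.exists():
                m = mz.read_stl(path)
                check(f"stl-watertight:{role}", m.is_watertight())

    grommet_rows = []
    for role, gs in report["grommets"].items():
        for g in gs:
            grommet_rows.append({"panel": role, **g})
    return {"pass": all(c["pass"] for c in checks), "checks": checks,
            "grommets": grommet_rows}
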
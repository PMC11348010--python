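"""Extrude 2D panel designs into watertight 3D solids and write STL.

Solids are represented as stacks of extruded cross-sections ("layers"):
each layer is a 2D region (shapely geometry) spanning a Z interval. The
mesher emits vertical walls along every ring and horizontal caps wherever
consecutive layers differ, inserting shared vertices so the result is
edge-watertight. This makes boolean assembly (grommets, ear slits, strap
holders) a 2D polygon problem — exact for extruded features like the
default grommet, and a documented slab approximation for arbitrary
library STLs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon

from . import mesh as mz
from .errors import (GeometryError, InvalidParameterError, LibraryError,
                     PlacementError, SolidGeometryError)
from .mesh import TriMesh
from .panel2d import PanelDesign
from .triangulate import triangulate_polygon

GRID = 1e-6           # snap grid for all 2D boolean results, mm
QUAD_SEGS = 3         # arc resolution for buffered beams

EXTRUDE_THICKNESS = 0.9


# ---------------------------------------------------------------------------
# layer stack -> watertight mesh
# ---------------------------------------------------------------------------


def _as_polys(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in geom.geoms if isinstance(g, Polygon) and g.area > 0]


def _snap(geom):
    return shapely.set_precision(geom, GRID)


def _oriented(poly: Polygon) -> Polygon:
    return shapely.geometry.polygon.orient(poly)        # exterior CCW, holes CW


def _ring_coords(ring) -> np.ndarray:
    c = np.asarray(ring.coords)[:, :2]
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    return c


def _refine_ring(coords: np.ndarray, candidates: np.ndarray,
                 tol: float = 20 * GRID) -> np.ndarray:
    """Insert candidate points that lie on ring segments (kills T-junctions)."""
    if len(candidates) == 0:
        return coords
    from scipy.spatial import cKDTree

    tree = cKDTree(candidates)
    out = []
    n = len(coords)
    for i in range(n):
        a, b = coords[i], coords[(i + 1) % n]
        out.append(a)
        d = b - a
        L = np.linalg.norm(d)
        if L < tol:
            continue
        near = tree.query_ball_point(0.5 * (a + b), 0.5 * L + 10 * tol)
        if not near:
            continue
        cand = candidates[near]
        t = ((cand - a) @ d) / (L * L)
        perp = np.linalg.norm(cand - (a + t[:, None] * d), axis=1)
        # keep clear of both endpoints so a corner candidate is never
        # inserted into two adjacent segments
        margin = tol / L
        sel = (t > margin) & (t < 1 - margin) & (perp < tol)
        if sel.any():
            order = np.argsort(t[sel])
            for p in cand[sel][order]:
                if np.linalg.norm(p - out[-1]) > tol and np.linalg.norm(p - b) > tol:
                    out.append(p)
    arr = np.array(out)
    # final consecutive dedup (same rule for every caller => consistent chains)
    keep = [0]
    for i in range(1, len(arr)):
        if np.linalg.norm(arr[i] - arr[keep[-1]]) > 1e-9:
            keep.append(i)
    if len(keep) > 1 and np.linalg.norm(arr[keep[-1]] - arr[keep[0]]) <= 1e-9:
        keep.pop()
    return arr[keep]


def _cap_triangles(ext: np.ndarray, holes: list[np.ndarray]) -> np.ndarray:
    """CCW triangles (k, 3, 2) covering the polygon, vertices only at input
    ring vertices. Constrained Delaunay (GEOS) with ear-clipping fallback."""
    poly = Polygon(ext, holes)
    target = abs(shapely.area(poly))
    try:
        cdt = shapely.constrained_delaunay_triangles(poly)
        tris = []
        total = 0.0
        for t in cdt.geoms:
            c = np.asarray(t.exterior.coords)[:3, :2]
            u, v = c[1] - c[0], c[2] - c[0]
            a = 0.5 * (u[0] * v[1] - u[1] * v[0])
            total += abs(a)
            tris.append(c if a >= 0 else c[::-1])
        if tris and abs(total - target) <= 1e-6 + 1e-9 * target:
            return np.array(tris)
    except Exception:
        pass
    v2, t2 = triangulate_polygon(ext, holes)
    return v2[t2]


def _patch_points(geom) -> np.ndarray:
    pts = []
    for poly in _as_polys(geom):
        pts.append(_ring_coords(poly.exterior))
        for ring in poly.interiors:
            pts.append(_ring_coords(ring))
    return np.vstack(pts) if pts else np.zeros((0, 2))


def stack_solid(layers: list[tuple[object, float, float]]) -> TriMesh:
    """Mesh a stack of extruded cross-sections into one watertight solid.

    `layers` are (2D geometry, z0, z1) with contiguous, increasing Z
    intervals. Raises SolidGeometryError if the result fails validation.
    """
    if not layers:
        raise SolidGeometryError("empty layer stack")
    layers = sorted(((shapely.union_all([_snap(g)]), float(z0), float(z1))
                     for g, z0, z1 in layers), key=lambda t: t[1])
    for g, z0, z1 in layers:
        if z1 <= z0:
            raise SolidGeometryError("layer with non-positive thickness")
        if g.is_empty:
            raise SolidGeometryError("layer with empty cross-section")
    for (g0, a0, b0), (g1, a1, b1) in zip(layers, layers[1:]):
        if abs(b0 - a1) > 1e-9:
            raise SolidGeometryError("layers are not contiguous in Z")

    # horizontal caps per interface
    caps = []                       # (geometry, z, facing_up)
    caps.append((layers[0][0], layers[0][1], False))
    for (g0, _, z), (g1, _, _) in zip(layers, layers[1:]):
        top = _snap(g0.difference(g1))
        bot = _snap(g1.difference(g0))
        if not top.is_empty:
            caps.append((top, z, True))
        if not bot.is_empty:
            caps.append((bot, z, False))
    caps.append((layers[-1][0], layers[-1][2], True))

    # one global candidate point set (all cap and layer boundary vertices):
    # inserted wherever it lies on a ring segment, so every wall and cap that
    # shares a boundary stretch conforms to the same vertex chain
    cand_list = [_patch_points(g) for g, _, _ in caps]
    cand_list += [_patch_points(g) for g, _, _ in layers]
    cand_all = np.unique(np.vstack([c for c in cand_list if len(c)]
                                   or [np.zeros((0, 2))]), axis=0)

    tri_v: list[np.ndarray] = []
    tri_f: list[tuple[int, int, int]] = []
    vid: dict[tuple[int, int, int], int] = {}

    def vert(x, y, z) -> int:
        key = (int(round(x / GRID)), int(round(y / GRID)), int(round(z / GRID)))
        if key not in vid:
            vid[key] = len(tri_v)
            tri_v.append(np.array([x, y, z]))
        return vid[key]

    def emit(a, b, c):
        if a != b and b != c and a != c:
            tri_f.append((a, b, c))

    # walls
    for g, z0, z1 in layers:
        for poly in _as_polys(g):
            poly = _oriented(poly)
            for ring in [poly.exterior] + list(poly.interiors):
                rc = _refine_ring(_ring_coords(ring), cand_all)
                n = len(rc)
                for i in range(n):
                    p, q = rc[i], rc[(i + 1) % n]
                    p0 = vert(p[0], p[1], z0)
                    q0 = vert(q[0], q[1], z0)
                    q1 = vert(q[0], q[1], z1)
                    p1 = vert(p[0], p[1], z1)
                    emit(p0, q0, q1)
                    emit(p0, q1, p1)

    # caps (ring refinement keeps cap boundaries conforming with the walls)
    for g, z, up in caps:
        for poly in _as_polys(g):
            poly = _oriented(poly)
            ext = _refine_ring(_ring_coords(poly.exterior), cand_all)
            holes = [_refine_ring(_ring_coords(r), cand_all) for r in poly.interiors]
            for tri in _cap_triangles(ext, holes):
                ids = [vert(p[0], p[1], z) for p in tri]
                if up:
                    emit(ids[0], ids[1], ids[2])
                else:
                    emit(ids[0], ids[2], ids[1])

    m = _weld(np.array(tri_v), np.array(tri_f, dtype=np.int64))
    if not m.is_watertight():
        raise SolidGeometryError("stacked solid is not watertight")
    if m.volume <= 0:
        raise SolidGeometryError("stacked solid has non-positive volume")
    return m


def _weld(V: np.ndarray, F: np.ndarray, tol: float = 2.5 * GRID) -> TriMesh:
    """Merge vertices closer than `tol` (snap-grid boundary stragglers) and
    drop the triangles that collapse."""
    from scipy.spatial import cKDTree

    pairs = cKDTree(V).query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(V))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    root = np.array([find(i) for i in range(len(V))])
    uniq, remap = np.unique(root, return_inverse=True)
    F2 = remap[F]
    ok = (F2[:, 0] != F2[:, 1]) & (F2[:, 1] != F2[:, 2]) & (F2[:, 0] != F2[:, 2])
    F2 = F2[ok]
    # cancel zero-volume membranes: pairs of coincident faces with opposite
    # winding (collapsed ribbon caps between welded walls)
    from collections import defaultdict

    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, f in enumerate(F2):
        groups[tuple(sorted(f))].append(i)
    def orient(f):
        f = list(f)
        k = f.index(min(f))
        return tuple(f[k:] + f[:k])

    drop = np.zeros(len(F2), dtype=bool)
    for idxs in groups.values():
        if len(idxs) < 2:
            continue
        buckets: dict[tuple, list[int]] = defaultdict(list)
        for i in idxs:
            buckets[orient(F2[i])].append(i)
        keys = sorted(buckets)
        if len(keys) == 2:
            for i, j in zip(buckets[keys[0]], buckets[keys[1]]):
                drop[i] = drop[j] = True
    return TriMesh(V[uniq], F2[~drop])


# ---------------------------------------------------------------------------
# solid panel
# ---------------------------------------------------------------------------


@dataclass
class SolidPanel:
    mesh: TriMesh
    layers: list[tuple[object, float, float]]
    manifest: dict = field(default_factory=dict)

    @property
    def volume(self) -> float:
        return self.mesh.volume

    def rebuild(self) -> None:
        self.mesh = stack_solid(self.layers)


def render_footprint(design: PanelDesign, lattice_width: float | None = None):
    """2D material footprint of a panel design (outline ring, beams, tabs)."""
    w = lattice_width if lattice_width is not None else (
        design.lattice.width if design.lattice else 0.85)
    parts = []
    parts.append(LineString(design.outline.exterior.coords)
                 .buffer(w / 2, quad_segs=QUAD_SEGS))
    if design.lattice is not None and len(design.lattice.beams):
        nodes = design.lattice.nodes
        for a, b in design.lattice.beams:
            parts.append(LineString([nodes[a], nodes[b]])
                         .buffer(w / 2, quad_segs=QUAD_SEGS))
    for t in design.tabs:
        parts.append(LineString(t.points).buffer(t.width / 2, quad_segs=QUAD_SEGS))
    return _snap(shapely.union_all(parts))


def extrude_panel(design: PanelDesign, thickness: float = EXTRUDE_THICKNESS) -> SolidPanel:
    """Extrude the rendered 2D design into a watertight solid in 0 <= Z <= t."""
    if thickness <= 0:
        raise InvalidParameterError("extrusion thickness must be positive")
    fp = render_footprint(design)
    if fp.is_empty:
        raise GeometryError("panel design renders to an empty footprint")
    layers = [(fp, 0.0, thickness)]
    mesh = stack_solid(layers)
    manifest = {
        "role": design.role,
        "thickness": thickness,
        "lattice_width": design.lattice.width if design.lattice else None,
        "tab_width": design.tabs[0].width if design.tabs else None,
        "grommets": [], "features": [],
        "tab_pairs": sorted({t.pair_id for t in design.tabs}),
    }
    return SolidPanel(mesh, layers, manifest)


# ---------------------------------------------------------------------------
# grommets
# ---------------------------------------------------------------------------


def make_default_grommet(inner_diameter: float = 11.0, outer_diameter: float = 16.0,
                         height: float = 5.0, segments: int = 48) -> TriMesh:
    """Annular-ring grommet solid, base at Z = 0, origin at the ring center."""
    if not 0 < inner_diameter < outer_diameter:
        raise InvalidParameterError("need 0 < inner diameter < outer diameter")
    if height <= 0:
        raise InvalidParameterError("grommet height must be positive")
    th = np.linspace(0, 2 * np.pi, segments, endpoint=False)
    outer = np.column_stack([np.cos(th), np.sin(th)]) * outer_diameter / 2
    inner = (np.column_stack([np.cos(th), np.sin(th)]) * inner_diameter / 2)[::-1]
    ann = Polygon(outer, [inner])
    return stack_solid([(_snap(ann), 0.0, height)])


@dataclass
class GrommetLibrary:
    """Directory of grommet solids: <root>/<#id>/grommet.stl."""

    root: Path
    _cache: dict[str, TriMesh] = field(default_factory=dict)

    def resolve(self, grommet_id: str) -> TriMesh:
        if grommet_id not in self._cache:
            path = Path(self.root) / grommet_id / "grommet.stl"
            if not path.exists():
                raise LibraryError(f"no grommet library entry for id {grommet_id!r} "
                                   f"(expected {path})")
            self._cache[grommet_id] = mz.read_stl(path)
        return self._cache[grommet_id]


def mesh_to_layers(mesh: TriMesh, max_slabs: int = 8) -> list[tuple[object, float, float]]:
    """Slab decomposition of a solid: exact for extrusions, approximate
    (uniform slabs with mid-slab cross-sections) otherwise."""
    z = mesh.vertices[:, 2]
    levels = np.unique(np.round(z, 6))
    if len(levels) > max_slabs:
        levels = np.linspace(z.min(), z.max(), max_slabs + 1)
    layers = []
    for z0, z1 in zip(levels, levels[1:]):
        zm = 0.5 * (z0 + z1)
        section = _cross_section(mesh, zm)
        if section is not None and not section.is_empty:
            layers.append((section, float(z0), float(z1)))
    if not layers:
        raise GeometryError("solid has no usable cross-sections")
    return layers


def _cross_section(mesh: TriMesh, z: float):
    try:
        polylines = mz.slice_plane(mesh, np.array([0, 0, z]), np.array([0, 0, 1.0]))
    except GeometryError:
        return None
    region = None
    rings = sorted((Polygon(pts[:, :2]) for pts, closed in polylines
                    if closed and len(pts) >= 3),
                   key=lambda p: -p.area)
    for p in rings:
        if not p.is_valid:
            p = p.buffer(0)
        region = p if region is None else region.symmetric_difference(p)
    return _snap(region) if region is not None else None


def _transform_2d(geom, rotation_deg: float, translate: np.ndarray):
    g = shapely.affinity.rotate(geom, rotation_deg, origin=(0, 0))
    return shapely.affinity.translate(g, float(translate[0]), float(translate[1]))


def merge_layer_stacks(stacks: list[list[tuple[object, float, float]]]
                       ) -> list[tuple[object, float, float]]:
    """Union several layer stacks into one contiguous stack."""
    zs = sorted({round(z, 9) for st in stacks for _, z0, z1 in st for z in (z0, z1)})
    out = []
    for z0, z1 in zip(zs, zs[1:]):
        zm = 0.5 * (z0 + z1)
        parts = [g for st in stacks for g, a, b in st if a - 1e-9 <= zm <= b + 1e-9]
        if parts:
            out.append((_snap(shapely.union_all(parts)), z0, z1))
    # contiguity: fill voids is not supported; stacking validates
    return out


def place_grommets(solid: SolidPanel, placements, library: GrommetLibrary,
                   thickness: float | None = None) -> SolidPanel:
    """Merge grommet solids at their 2D coordinates (base flush with the
    panel top) and punch their through-holes down through the panel."""
    if not placements:
        return solid
    t = thickness if thickness is not None else max(z1 for _, _, z1 in solid.layers)
    stacks = [list(solid.layers)]
    holes = []
    for g in placements:
        gm = library.resolve(g.grommet_id)
        glayers = mesh_to_layers(gm)
        z_base = min(z0 for _, z0, _ in glayers)
        placed = []
        for geom, z0, z1 in glayers:
            g2 = _transform_2d(geom, g.rotation, np.asarray(g.position, dtype=float))
            placed.append((_snap(g2), z0 - z_base + t, z1 - z_base + t))
        stacks.append(placed)
        # punch the base cross-section holes through the panel
        base_geom = placed[0][0]
        for poly in _as_polys(base_geom):
            for ring in poly.interiors:
                holes.append(_transform_2d(Polygon(ring), 0.0, np.zeros(2)))
        solid.manifest["grommets"].append({
            "grommet": g.grommet_id,
            "position": [float(x) for x in g.position],
            "rotation": float(g.rotation),
            "optode": g.optode, "flags": list(g.flags),
        })
    if holes:
        hole_geom = shapely.union_all(holes)
        stacks[0] = [(_snap(geom.difference(hole_geom)), z0, z1)
                     for geom, z0, z1 in stacks[0]]
    layers = merge_layer_stacks(stacks)
    out = SolidPanel(stack_solid(layers), layers, solid.manifest)
    return out


# ---------------------------------------------------------------------------
# ear slits and strap holders
# ---------------------------------------------------------------------------


def _stadium(center: np.ndarray, axis: np.ndarray, length: float, width: float) -> Polygon:
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    half = 0.5 * (length - width)
    if half <= 0:
        return Point(center).buffer(width / 2, quad_segs=8)
    return LineString([center - axis * half, center + axis * half]).buffer(
        width / 2, quad_segs=8)


def add_ear_slit(solid: SolidPanel, flat_ear_point: np.ndarray,
                 up_dir: np.ndarray, rear_dir: np.ndarray,
                 offset: float = 15.0, slant_deg: float = 20.0,
                 length: float = 34.0, width: float = 18.0,
                 ring_width: float = 2.5) -> SolidPanel:
    """Stamp a backward-slanted stadium ear slit 15 mm up from the flattened
    LPA/RPA point and add a reinforcing outline ring around it."""
    p = np.asarray(flat_ear_point, dtype=float)
    up = np.asarray(up_dir, dtype=float)
    up = up / max(np.linalg.norm(up), 1e-12)
    rear = np.asarray(rear_dir, dtype=float)
    rear = rear / max(np.linalg.norm(rear), 1e-12)
    center = p + offset * up
    a = np.radians(slant_deg)
    axis = np.cos(a) * up + np.sin(a) * rear
    hole = _snap(_stadium(center, axis, length, width))
    ring = _snap(hole.buffer(ring_width).difference(hole))

    # stamp the hole out of every layer; the reinforcing ring only joins the
    # base (panel-thickness) layer
    zmin = min(z0 for _, z0, _ in solid.layers)
    new_layers = []
    for geom, z0, z1 in solid.layers:
        g = geom.difference(hole)
        if z0 <= zmin + 1e-9:
            g = shapely.union_all([g, ring])
        new_layers.append([_snap(g), z0, z1])

    base = new_layers[0][0]
    big = [pp for pp in _as_polys(base) if pp.area > 1.0]
    if len(big) > 1:
        raise GeometryError("ear slit would sever the panel into "
                            f"{len(big)} components")
    layers = [(g, z0, z1) for g, z0, z1 in new_layers]
    out = SolidPanel(stack_solid(layers), layers, solid.manifest)
    out.manifest.setdefault("features", []).append({
        "type": "ear_slit",
        "center": [float(x) for x in center],
        "ear_point": [float(x) for x in p],
        "up": [float(x) for x in up], "rear": [float(x) for x in rear],
        "offset": float(offset), "slant_deg": float(slant_deg),
        "hole_area": float(hole.area),
        "template_length": length, "template_width": width,
    })
    return out


def add_strap_holders(solid: SolidPanel, holders: list[dict],
                      slot_length: float = 16.0, slot_width: float = 7.0,
                      ring_width: float = 3.0) -> SolidPanel:
    """Merge slotted-loop strap holders at the given positions.

    Each holder dict: {"center": (2,), "axis": (2,), "name": str}.
    """
    base = solid.layers[0][0]
    new_layers = [list(L) for L in solid.layers]
    for h in holders:
        center = np.asarray(h["center"], dtype=float)
        axis = np.asarray(h["axis"], dtype=float)
        slot = _stadium(center, axis, slot_length, slot_width)
        outer = _stadium(center, axis, slot_length + 2 * ring_width,
                         slot_width + 2 * ring_width)
        ring = _snap(outer.difference(slot))
        if not ring.intersects(base):
            raise PlacementError(
                f"strap holder {h.get('name', '?')!r} does not touch the panel")
        zmin = min(z0 for _, z0, _ in solid.layers)
        for L in new_layers:
            L[0] = L[0].difference(slot)
            if L[1] <= zmin + 1e-9:
                L[0] = shapely.union_all([L[0], ring])
            L[0] = _snap(L[0])
        solid.manifest.setdefault("features", []).append({
            "type": "strap_holder", "name": h.get("name", ""),
            "center": [float(x) for x in center],
            "axis": [float(x) for x in axis / max(np.linalg.norm(axis), 1e-12)],
        })
    layers = [(g, z0, z1) for g, z0, z1 in new_layers]
    return SolidPanel(stack_solid(layers), layers, solid.manifest)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_stl(solid: SolidPanel | TriMesh, path, mode: str = "binary") -> None:
    mesh = solid.mesh if isinstance(solid, SolidPanel) else solid
    mz.write_stl(mesh, path, mode=mode)


def write_manifest(solid: SolidPanel, path) -> None:
    with open(path, "w") as fh:
        json.dump(solid.manifest, fh, indent=1)


def validate_solid(mesh: TriMesh) -> dict:
    return {
        "watertight": mesh.is_watertight(),
        "volume": mesh.volume,
        "positive_volume": mesh.volume > 0,
        "z_extent": [float(mesh.vertices[:, 2].min()), float(mesh.vertices[:, 2].max())],
        "triangles": int(len(mesh.faces)),
    }
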
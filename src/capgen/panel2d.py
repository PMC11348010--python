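"""2D panel designs: outlines, hexagonal lattice fill, mid-panel halving,
and welding tabs along the virtual seams.

Default print parameters: hexagon edge 10 mm, lattice beam width 0.85 mm,
welding tab width 2 mm. Seam correspondence across panels uses a common
arc-length parameter (derived from the shared 3D cut line), so tabs from
neighbouring panels can be repositioned to a shared intermediate point and
extended past each other into overlapping pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split

from .errors import GeometryError, TopologyError
from .flattening import FlatMesh, OPTODE_PREFIX
from .surface_prep import PanelSurface

HEX_EDGE = 10.0
LATTICE_WIDTH = 0.85
TAB_WIDTH = 2.0
TAB_REACH = 10.0

#: Side-panel lower outline template: (x, y) control points in mm for a
#: nominal 180 mm wide panel; x runs front -> back along the upper-outline
#: chord, y is the drop below it (chin dip, ear region, neck rise). The
#: curve is stretched laterally so its endpoints meet the upper outline.
SIDE_TEMPLATE_NATIVE_WIDTH = 180.0
SIDE_TEMPLATE_POINTS = (
    (0.0, 0.0), (12.0, -30.0), (30.0, -48.0), (55.0, -40.0), (80.0, -52.0),
    (105.0, -55.0), (130.0, -45.0), (155.0, -28.0), (170.0, -12.0), (180.0, 0.0),
)


@dataclass
class Seam:
    """A virtual seam polyline in panel coordinates with a cross-panel
    arc-length parameter `s` (shared with the neighbouring panel)."""

    name: str
    points: np.ndarray              # (k, 2)
    s: np.ndarray                   # (k,) monotone increasing

    def point_at(self, sv: float) -> np.ndarray:
        sv = float(np.clip(sv, self.s[0], self.s[-1]))
        i = int(np.searchsorted(self.s, sv, side="right") - 1)
        i = min(max(i, 0), len(self.s) - 2)
        ds = self.s[i + 1] - self.s[i]
        t = (sv - self.s[i]) / ds if ds > 0 else 0.0
        return self.points[i] + t * (self.points[i + 1] - self.points[i])

    def locate(self, p) -> tuple[float, float]:
        """(s, perpendicular distance) of the projection of p onto the seam."""
        p = np.asarray(p, dtype=float)
        a = self.points[:-1]
        d = self.points[1:] - a
        L2 = np.einsum("ij,ij->i", d, d)
        L2s = np.where(L2 > 0, L2, 1.0)
        t = np.clip(np.einsum("ij,ij->i", p - a, d) / L2s, 0.0, 1.0)
        q = a + t[:, None] * d
        dist = np.linalg.norm(q - p, axis=1)
        i = int(np.argmin(dist))
        sv = self.s[i] + t[i] * (self.s[i + 1] - self.s[i])
        return float(sv), float(dist[i])


@dataclass
class Lattice:
    nodes: np.ndarray               # (n, 2)
    beams: np.ndarray               # (m, 2) node indices
    width: float = LATTICE_WIDTH

    def beam_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[self.beams[:, 0]] - self.nodes[self.beams[:, 1]],
                              axis=1)


@dataclass
class GrommetPlacement:
    position: np.ndarray            # (2,) mm in panel frame
    rotation: float                 # deg about +Z
    grommet_id: str
    optode: str = ""                # marker name
    flags: list[str] = field(default_factory=list)


@dataclass
class Tab:
    points: np.ndarray              # (k, 2) polyline, ends beyond the seam
    width: float
    pair_id: str
    partner_role: str
    merged: bool = False
    grommet_extended: bool = False


@dataclass
class PanelDesign:
    role: str                       # left / right / mid-front / mid-back
    outline: Polygon
    lattice: Lattice | None = None
    grommets: list[GrommetPlacement] = field(default_factory=list)
    tabs: list[Tab] = field(default_factory=list)
    seams: dict[str, Seam] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "outline": np.asarray(self.outline.exterior.coords).tolist(),
            "lattice": None if self.lattice is None else {
                "nodes": self.lattice.nodes.tolist(),
                "beams": self.lattice.beams.tolist(),
                "width": self.lattice.width,
            },
            "grommets": [{"position": g.position.tolist(), "rotation": g.rotation,
                          "grommet": g.grommet_id, "optode": g.optode, "flags": g.flags}
                         for g in self.grommets],
            "tabs": [{"points": t.points.tolist(), "width": t.width, "pair_id": t.pair_id,
                      "partner": t.partner_role, "merged": t.merged,
                      "grommet_extended": t.grommet_extended} for t in self.tabs],
            "meta": {k: v for k, v in self.meta.items() if _jsonable(v)},
        }


def _jsonable(v) -> bool:
    import json

    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# hexagonal lattice
# ---------------------------------------------------------------------------


def hex_fill(outline: Polygon, edge: float = HEX_EDGE,
             width: float = LATTICE_WIDTH) -> Lattice:
    """Fill `outline` with a regular pointy-top hexagonal lattice.

    Interior beams have length exactly `edge`; boundary-crossing beams are
    trimmed at the outline so their ends lie on the outline ring.
    """
    if edge <= 0 or width <= 0:
        raise GeometryError("hex edge and width must be positive")
    if not outline.is_valid or outline.area <= 0:
        raise GeometryError("outline polygon is invalid")

    minx, miny, maxx, maxy = outline.bounds
    dx = np.sqrt(3.0) * edge
    dy = 1.5 * edge
    j0 = int(np.floor((miny - 2 * edge) / dy)) - 1
    j1 = int(np.ceil((maxy + 2 * edge) / dy)) + 1
    i0 = int(np.floor((minx - 2 * edge) / dx)) - 1
    i1 = int(np.ceil((maxx + 2 * edge) / dx)) + 1

    ang = np.radians([90, 150, 210, 270, 330, 30])
    corner_off = edge * np.column_stack([np.cos(ang), np.sin(ang)])

    node_ids: dict[tuple[int, int], int] = {}
    nodes: list[np.ndarray] = []
    edges_set: set[tuple[int, int]] = set()

    def node_id(p: np.ndarray) -> int:
        key = (int(round(p[0] * 1e6)), int(round(p[1] * 1e6)))
        if key not in node_ids:
            node_ids[key] = len(nodes)
            nodes.append(p)
        return node_ids[key]

    raw_edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    raw_pts: dict[tuple[int, int], np.ndarray] = {}
    for j in range(j0, j1 + 1):
        cy = dy * j
        xoff = 0.5 * dx if (j % 2) else 0.0
        for i in range(i0, i1 + 1):
            cx = dx * i + xoff
            corners = corner_off + np.array([cx, cy])
            keys = []
            for p in corners:
                k = (int(round(p[0] * 1e6)), int(round(p[1] * 1e6)))
                raw_pts[k] = p
                keys.append(k)
            for k in range(6):
                a, b = keys[k], keys[(k + 1) % 6]
                raw_edges.add((a, b) if a <= b else (b, a))

    # tiny positive buffer keeps beams that lie exactly on the outline ring
    clip_region = outline.buffer(1e-9, quad_segs=1)
    prep = shapely.prepared.prep(clip_region)
    for ka, kb in sorted(raw_edges):
        pa, pb = raw_pts[ka], raw_pts[kb]
        seg = LineString([pa, pb])
        if prep.contains_properly(seg) or prep.covers(seg):
            edges_set.add(tuple(sorted((node_id(pa), node_id(pb)))))
            continue
        if not prep.intersects(seg):
            continue
        inter = clip_region.intersection(seg)
        for geom in getattr(inter, "geoms", [inter]):
            if isinstance(geom, LineString) and geom.length > 1e-3:
                c = np.asarray(geom.coords)
                for k in range(len(c) - 1):
                    edges_set.add(tuple(sorted((node_id(c[k]), node_id(c[k + 1])))))

    if not nodes:
        raise GeometryError("outline is smaller than one hexagon; no lattice fits")
    nodes_arr = np.array(nodes)
    beams = np.array(sorted(edges_set), dtype=np.int64)
    if len(beams) == 0:
        raise GeometryError("outline is smaller than one hexagon; no lattice fits")

    beams = _keep_ring_connected(nodes_arr, beams, outline)
    return Lattice(nodes_arr, beams, width)


def _keep_ring_connected(nodes: np.ndarray, beams: np.ndarray, outline: Polygon) -> np.ndarray:
    """Drop lattice components not connected to the outline ring."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    g.add_edges_from(map(tuple, beams))
    ring = outline.exterior
    on_ring = {i for i in range(len(nodes))
               if ring.distance(Point(nodes[i])) < 1e-6}
    if not on_ring:
        # nothing touches the boundary: keep the largest component
        comp = max(nx.connected_components(g), key=len)
        keep = comp
    else:
        keep = set()
        for comp in nx.connected_components(g):
            if comp & on_ring:
                keep |= comp
    mask = np.array([a in keep and b in keep for a, b in beams])
    return beams[mask]


# ---------------------------------------------------------------------------
# outlines
# ---------------------------------------------------------------------------


def _ordered_boundary_xy(flat: FlatMesh) -> np.ndarray:
    loops = flat.mesh2d().boundary_loops()
    if len(loops) != 1:
        raise TopologyError(f"expected one boundary loop, found {len(loops)}")
    return flat.xy[loops[0]], loops[0]


def _seam_polyline(flat: FlatMesh, panel: PanelSurface, label: str) -> tuple[np.ndarray, np.ndarray]:
    """(2D points, common 3D arc-length parameter) for a labeled cut boundary.

    The parameter runs from the back (min 3D Y) end so neighbouring panels
    agree on it."""
    chain = panel.boundary_polyline(label)
    pts3 = panel.mesh.vertices[chain]
    if pts3[0, 1] > pts3[-1, 1]:
        chain = chain[::-1]
        pts3 = pts3[::-1]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts3, axis=0), axis=1))])
    return flat.xy[chain], s


def build_mid_outlines(flat_mid: FlatMesh, panel_mid: PanelSurface,
                       grommets: list[GrommetPlacement] | None = None,
                       midline_tol: float = 1e-5) -> tuple[PanelDesign, PanelDesign]:
    """Trace the flattened mid-panel outline and split it along the midline.

    Returns (front, back) PanelDesign shells (outline + seams + grommets,
    lattice not yet filled). Grommets exactly on the halving line go to the
    front half and are flagged.
    """
    boundary_xy, _ = _ordered_boundary_xy(flat_mid)
    poly = Polygon(boundary_xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area <= 0:
        raise TopologyError("mid panel outline is degenerate")
    poly = shapely.geometry.polygon.orient(poly)

    V3 = panel_mid.mesh.vertices
    mid_ids = np.nonzero(np.abs(V3[:, 0]) < midline_tol)[0]
    if len(mid_ids) < 2:
        raise TopologyError("mid panel has no midline vertex chain")
    order = np.argsort(-V3[mid_ids, 1])          # front (max Y) -> back
    mid_ids = mid_ids[order]
    mid_xy = flat_mid.xy[mid_ids]

    # extend the halving line beyond the outline so the split is clean
    d0 = mid_xy[0] - mid_xy[1]
    d1 = mid_xy[-1] - mid_xy[-2]
    d0 = d0 / max(np.linalg.norm(d0), 1e-12)
    d1 = d1 / max(np.linalg.norm(d1), 1e-12)
    ext = 0.2 * np.sqrt(poly.area)
    cut_line = LineString(np.vstack([mid_xy[0] + d0 * ext, mid_xy, mid_xy[-1] + d1 * ext]))

    pieces = [g for g in shapely_split(poly, cut_line).geoms if isinstance(g, Polygon)]
    if len(pieces) != 2:
        raise TopologyError(f"midline split produced {len(pieces)} pieces (expected 2)")

    def mean_y3(piece: Polygon) -> float:
        inside = shapely.contains_xy(piece.buffer(1e-6), flat_mid.xy[:, 0], flat_mid.xy[:, 1])
        sel = inside & (np.abs(V3[:, 0]) > midline_tol)
        return float(V3[sel, 1].mean()) if sel.any() else -np.inf

    front_poly, back_poly = sorted(pieces, key=mean_y3, reverse=True)

    s_mid = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(mid_xy, axis=0), axis=1))])
    seam_mid = lambda: Seam("midline", mid_xy.copy(), s_mid.copy())  # noqa: E731
    sag_l = _seam_polyline(flat_mid, panel_mid, "sagittal-left")
    sag_r = _seam_polyline(flat_mid, panel_mid, "sagittal-right")

    front = PanelDesign("mid-front", front_poly,
                        seams={"midline": seam_mid(),
                               "sagittal-left": Seam("sagittal-left", *sag_l),
                               "sagittal-right": Seam("sagittal-right", *sag_r)})
    back = PanelDesign("mid-back", back_poly,
                       seams={"midline": seam_mid(),
                              "sagittal-left": Seam("sagittal-left", *sag_l),
                              "sagittal-right": Seam("sagittal-right", *sag_r)})

    for g in grommets or []:
        p = Point(g.position)
        on_line = cut_line.distance(p) < 1e-9
        if on_line:
            g.flags.append("on-midline:assigned-front")
            front.grommets.append(g)
        elif front_poly.buffer(1e-9).covers(p):
            front.grommets.append(g)
        else:
            back.grommets.append(g)
    return front, back


def build_side_outline(flat_side: FlatMesh, panel_side: PanelSurface,
                       template_points=SIDE_TEMPLATE_POINTS,
                       template_native_width: float = SIDE_TEMPLATE_NATIVE_WIDTH,
                       n_samples: int = 80) -> PanelDesign:
    """Side panel outline: flattened sagittal cut line on top, laterally
    stretched template curve (chin / ear / neck) below."""
    role = panel_side.role
    label = "sagittal-left" if role == "left" else "sagittal-right"
    seam_xy, seam_s = _seam_polyline(flat_side, panel_side, label)

    a, b = seam_xy[0], seam_xy[-1]
    w = float(np.linalg.norm(b - a))
    if w < 1e-6:
        raise GeometryError("degenerate flat side panel: seam endpoints coincide")
    stretch = w / template_native_width
    e_hat = (b - a) / w
    n_hat = np.array([e_hat[1], -e_hat[0]])
    # template must point away from the panel interior
    centroid = seam_xy.mean(axis=0)
    mid_ab = 0.5 * (a + b)
    if np.dot(centroid - mid_ab, n_hat) > 0:
        n_hat = -n_hat

    from scipy.interpolate import PchipInterpolator

    tp = np.asarray(template_points, dtype=float)
    f = PchipInterpolator(tp[:, 0], tp[:, 1])
    xs = np.linspace(tp[0, 0], tp[-1, 0], n_samples)
    depth = -f(xs)                      # template y is a drop; n_hat points away
    lower = (a[None, :] + (xs * stretch)[:, None] * e_hat[None, :]
             + depth[:, None] * n_hat[None, :])

    ring = np.vstack([seam_xy, lower[::-1][1:-1]])
    poly = Polygon(ring)
    if not poly.is_valid:
        fixed = poly.buffer(0)          # folded micro-needles on the seam line
        if isinstance(fixed, Polygon) and fixed.area > 0.999 * abs(Polygon(ring).area):
            poly = fixed
        else:
            raise GeometryError("side outline self-intersects; adjust the template")
    poly = shapely.geometry.polygon.orient(poly)

    design = PanelDesign(role, poly, seams={label: Seam(label, seam_xy, seam_s)})
    design.meta["template_stretch"] = stretch
    design.meta["upper_outline_width"] = w
    design.meta["seam_label"] = label
    return design


# ---------------------------------------------------------------------------
# welding tabs
# ---------------------------------------------------------------------------


@dataclass
class _Candidate:
    design: PanelDesign
    beam_index: int
    seam_node: int                  # lattice node on the seam
    inner_node: int                 # lattice node inside the panel
    s: float                        # seam parameter of the seam end
    d: float                        # distance of the inner node from the seam


def _collect_candidates(design: PanelDesign, seam_name: str,
                        reach: float, on_tol: float = 0.05) -> list[_Candidate]:
    seam = design.seams[seam_name]
    lat = design.lattice
    if lat is None:
        return []
    out = []
    for bi, (i, j) in enumerate(lat.beams):
        si, di = seam.locate(lat.nodes[i])
        sj, dj = seam.locate(lat.nodes[j])
        oni, onj = di < on_tol, dj < on_tol
        if oni == onj:
            continue
        seam_node, inner_node = (i, j) if oni else (j, i)
        s_on = si if oni else sj
        d_in = dj if oni else di
        if d_in > 1.5 * reach:
            continue
        out.append(_Candidate(design, bi, int(seam_node), int(inner_node),
                              float(s_on), float(d_in)))
    out.sort(key=lambda c: (c.s, c.inner_node))
    return out


def _inward_normal(design: PanelDesign, seam: Seam, sv: float) -> np.ndarray:
    p = seam.point_at(sv)
    p2 = seam.point_at(min(sv + 1.0, float(seam.s[-1])))
    if np.allclose(p2, p):
        p2 = seam.point_at(max(sv - 1.0, float(seam.s[0])))
        t = p - p2
    else:
        t = p2 - p
    t = t / max(np.linalg.norm(t), 1e-12)
    n = np.array([-t[1], t[0]])
    probe = p + 0.75 * n
    if not design.outline.covers(Point(probe)):
        n = -n
    return n


def generate_weld_tabs(panel_a: PanelDesign, panel_b,
                       seam_name: str,
                       tab_width: float = TAB_WIDTH,
                       reach: float = TAB_REACH,
                       hex_edge: float = HEX_EDGE) -> dict:
    """Create overlapping welding-tab pairs across a seam.

    `panel_b` may be a single design or a list (the mid panel halves share
    the sagittal seam with one side panel). Seam-touching lattice beams are
    paired by closest seam parameter, repositioned to the shared intermediate
    point, and extended past the partner's end node. Unequal counts merge
    two tabs onto one partner; grommets within one hex edge of the seam
    extend the overlapping partner tab to the next lattice node beyond.

    Returns a report: pair table + unpaired warnings.
    """
    b_list = panel_b if isinstance(panel_b, (list, tuple)) else [panel_b]
    cand_a = _collect_candidates(panel_a, seam_name, reach)
    cand_b = [c for d in b_list for c in _collect_candidates(d, seam_name, reach)]
    cand_b.sort(key=lambda c: (c.s, c.inner_node))

    report = {"seam": seam_name, "pairs": [], "unpaired": [], "merged": 0,
              "grommet_extensions": []}
    if not cand_a or not cand_b:
        for c in cand_a + cand_b:
            report["unpaired"].append({"role": c.design.role, "s": c.s})
        return report

    # pair by seam parameter
    groups: list[list[_Candidate]] = []
    if len(cand_a) == len(cand_b):
        groups = [[x, y] for x, y in zip(cand_a, cand_b)]
    else:
        longer, shorter = (cand_a, cand_b) if len(cand_a) > len(cand_b) else (cand_b, cand_a)
        buckets: dict[int, list[_Candidate]] = {i: [s] for i, s in enumerate(shorter)}
        s_short = np.array([c.s for c in shorter])
        for c in longer:
            i = int(np.argmin(np.abs(s_short - c.s)))
            buckets[i].append(c)
        groups = [buckets[i] for i in sorted(buckets)]

    # drop hopeless pairings (too far along the seam, or no cross-panel partner)
    ok_groups = []
    for g in groups:
        smin = min(c.s for c in g)
        smax = max(c.s for c in g)
        if smax - smin > 2.0 * reach or len({id(c.design) for c in g}) < 2:
            for c in g:
                report["unpaired"].append({"role": c.design.role, "s": c.s})
            continue
        ok_groups.append(g)

    # grommets near the seam (per design)
    near_grommets = []
    for d in [panel_a] + list(b_list):
        seam = d.seams[seam_name]
        for g in d.grommets:
            sv, dist = seam.locate(g.position)
            if dist <= hex_edge:
                near_grommets.append((d, g, sv, dist))
                if "near-seam" not in g.flags:
                    g.flags.append("near-seam")

    to_remove: dict[int, set[int]] = {}
    for gi, group in enumerate(ok_groups):
        s_star = float(np.mean([c.s for c in group]))
        pair_id = f"{seam_name}:{gi}"
        merged = len(group) > 2
        if merged:
            report["merged"] += 1
        sides = {}
        for c in group:
            sides.setdefault(id(c.design), []).append(c)
        for c in group:
            partners = [o for o in group if o.design is not c.design]
            ext = max((o.d for o in partners), default=c.d)
            gext = False
            # grommet-near-seam: extend the overlapping tab to the next
            # lattice node beyond the grommet on the partner's side
            for (gd, g, gsv, gdist) in near_grommets:
                if gd is c.design or abs(gsv - s_star) > 0.75 * hex_edge:
                    continue
                ext2 = _next_node_offset(gd, seam_name, gsv, gdist, hex_edge)
                if ext2 > ext:
                    ext = ext2
                gext = True
                report["grommet_extensions"].append(
                    {"pair": pair_id, "panel": c.design.role, "optode": g.optode})
            seam = c.design.seams[seam_name]
            base = seam.point_at(s_star)
            n_in = _inward_normal(c.design, seam, s_star)
            inner = c.design.lattice.nodes[c.inner_node]
            pts = np.array([inner, base, base - n_in * ext])
            c.design.tabs.append(Tab(pts, tab_width, pair_id,
                                     partner_role="+".join(sorted(
                                         {o.design.role for o in partners})) or c.design.role,
                                     merged=merged, grommet_extended=gext))
            to_remove.setdefault(id(c.design), set()).add(c.beam_index)
        report["pairs"].append({
            "pair_id": pair_id, "s": s_star, "merged": merged,
            "members": [{"role": c.design.role, "s": c.s, "d": c.d} for c in group]})

    # strip the replaced stub beams from each lattice
    for d in [panel_a] + list(b_list):
        rm = to_remove.get(id(d))
        if rm:
            keep = np.array([i not in rm for i in range(len(d.lattice.beams))])
            d.lattice.beams = d.lattice.beams[keep]
    return report


def _next_node_offset(design: PanelDesign, seam_name: str, gsv: float,
                      gdist: float, hex_edge: float) -> float:
    """Perpendicular offset of the first lattice node beyond the grommet."""
    seam = design.seams[seam_name]
    lat = design.lattice
    best = None
    for i, p in enumerate(lat.nodes):
        sv, dist = seam.locate(p)
        if abs(sv - gsv) > 0.75 * hex_edge:
            continue
        if dist > gdist + 1e-6:
            if best is None or dist < best:
                best = dist
    return float(best) if best is not None else gdist + hex_edge


# ---------------------------------------------------------------------------
# connectivity check used by verify + tests
# ---------------------------------------------------------------------------


def design_components(design: PanelDesign) -> int:
    """Connected components of lattice + outline ring + tabs (1 == sound)."""
    import networkx as nx

    g = nx.Graph()
    lat = design.lattice
    if lat is not None:
        g.add_nodes_from(range(len(lat.nodes)))
        g.add_edges_from(map(tuple, lat.beams))
        ring = design.outline.exterior
        on_ring = [i for i in range(len(lat.nodes))
                   if ring.distance(Point(lat.nodes[i])) < 1e-6]
        order = sorted(on_ring, key=lambda i: ring.project(Point(lat.nodes[i])))
        for a, b in zip(order, order[1:] + order[:1]):
            g.add_edge(a, b)
    for t in design.tabs:
        # tabs start at a lattice node
        if lat is not None and len(lat.nodes):
            d = np.linalg.norm(lat.nodes - t.points[0], axis=1)
            g.add_edge(int(np.argmin(d)), f"tab:{t.pair_id}:{id(t)}")
    if g.number_of_nodes() == 0:
        return 0
    return nx.number_connected_components(g)
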
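"""Embed landmark/probe points as mesh vertices and cut the head into panels.

The axial cut plane passes through Iz and the point 15 mm superior of Nz
(lateral normal); everything below is discarded. Two sagittal planes at
X = +-x0 then split the upper surface into left / mid / right panel
surfaces, with x0 chosen so the central coronal arc between the planes is
`mid_fraction` (default 3/7) of the whole LPA-Cz-RPA arc. The mid panel is
halved along the midline later, in 2D, after flattening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mesh as mz
from .errors import GeometryError, PlacementError
from .headmodel import HeadMesh, LandmarkSet, slice_arc
from .mesh import TriMesh

PANEL_ROLES = ("left", "mid", "right")
PLANE_TOL = 1e-5


@dataclass
class PanelSurface:
    """A cut-out piece of the scalp surface destined for one printed panel."""

    mesh: TriMesh
    provenance: np.ndarray               # per-vertex original head vertex id, -1 = cut
    role: str
    boundary_vertex_labels: dict[int, str] = field(default_factory=dict)
    markers: dict[str, int] = field(default_factory=dict)   # name -> panel vertex id
    boundary_edge_map: dict[tuple[int, int], str] = field(default_factory=dict)

    def boundary_edge_labels(self) -> list[tuple[int, int, str]]:
        """Boundary edges labeled by the cut they lie on."""
        out = []
        for a, b in self.mesh.boundary_edges():
            key = (min(int(a), int(b)), max(int(a), int(b)))
            if key in self.boundary_edge_map:
                label = self.boundary_edge_map[key]
            else:
                la = self.boundary_vertex_labels.get(int(a))
                lb = self.boundary_vertex_labels.get(int(b))
                label = la if (la == lb and la is not None) else (la or lb or "rim")
            out.append((int(a), int(b), label))
        return out

    def boundary_polyline(self, label: str) -> np.ndarray:
        """Ordered vertex indices of the boundary section carrying `label`."""
        import networkx as nx

        edges = [(a, b) for a, b, lbl in self.boundary_edge_labels() if lbl == label]
        if not edges:
            raise GeometryError(f"panel {self.role!r} has no {label!r} boundary")
        g = nx.Graph(edges)
        ends = [n for n in g.nodes if g.degree(n) == 1]
        if len(ends) >= 2:
            start = min(ends)
            path = [start]
            prev = None
            cur = start
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            return np.array(path, dtype=np.int64)
        # closed section: return the cycle
        cyc = nx.find_cycle(g)
        return np.array([a for a, _ in cyc], dtype=np.int64)


@dataclass
class CutResult:
    panels: dict[str, PanelSurface]
    x0: float
    discarded_area: float
    axial_plane: tuple[np.ndarray, np.ndarray]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def embed_points(head: HeadMesh, points: dict[str, np.ndarray],
                 max_dist: float = 0.5) -> tuple[HeadMesh, dict[str, int]]:
    """Insert each labeled point as an exact mesh vertex.

    Returns the refined head and a map label -> vertex index. Insertion is
    area preserving (points are snapped to the surface first) and fiducial
    indices are remapped transparently (they never move: existing vertices
    keep their indices because insertion only appends).
    """
    m = head.mesh
    ids: dict[str, int] = {}
    for label in points:
        m, vid = mz.embed_point(m, np.asarray(points[label], dtype=float), max_dist=max_dist)
        ids[label] = vid
    return HeadMesh(m, dict(head.fiducials)), ids


# ---------------------------------------------------------------------------
# cutting
# ---------------------------------------------------------------------------


def sagittal_cut_offset(head: HeadMesh, landmarks: LandmarkSet,
                        mid_fraction: float = 3.0 / 7.0,
                        mode: str = "arc") -> float:
    """x0 such that the central coronal-arc portion with |X| <= x0 is
    `mid_fraction` of the whole LPA-Cz-RPA arc ("arc" mode), or the chord
    interpretation ("euclidean")."""
    if not 0 < mid_fraction < 1:
        raise GeometryError("mid_fraction must be in (0, 1)")
    lpa, rpa, cz = (np.asarray(landmarks.point(k), dtype=float)
                    for k in ("LPA", "RPA", "Cz"))
    if mode == "euclidean":
        return 0.5 * mid_fraction * float(np.linalg.norm(rpa - lpa))
    arc = slice_arc(head.mesh, (lpa, rpa, cz), lpa, rpa, via=cz)
    seg = np.diff(arc, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    xa, xb = arc[:-1, 0], arc[1:, 0]
    total = seglen.sum()
    target = mid_fraction * total

    def central(x0):
        # exact length of the |x| <= x0 portion, prorating split segments
        lo = np.minimum(xa, xb)
        hi = np.maximum(xa, xb)
        overlap = np.clip(np.minimum(hi, x0) - np.maximum(lo, -x0), 0.0, None)
        span = hi - lo
        frac = np.where(span > 1e-12, overlap / np.where(span > 1e-12, span, 1.0),
                        (np.abs(0.5 * (xa + xb)) <= x0).astype(float))
        return float((seglen * frac).sum())

    lo, hi = 0.0, float(np.abs(arc[:, 0]).max())
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if central(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _axial_plane(head: HeadMesh, axial_offset: float):
    nz, iz = head.fiducial_point("Nz"), head.fiducial_point("Iz")
    front = nz + np.array([0.0, 0.0, axial_offset])
    v = front - iz
    n = np.cross(np.array([1.0, 0.0, 0.0]), v)
    n = n / np.linalg.norm(n)
    cz_up = head.mesh.vertices[:, 2].max()
    if np.dot(n, np.array([0.0, 0.0, cz_up]) - iz) < 0:
        n = -n
    return iz, n


def axial_cut_marker_points(head: HeadMesh, axial_offset: float = 15.0) -> dict[str, np.ndarray]:
    """Points where the axial cut line passes directly above LPA / RPA.

    These are embedded as vertices so the ear-slit anchor survives the cut
    (LPA itself lies below the axial plane and is discarded).
    """
    origin, normal = _axial_plane(head, axial_offset)
    out = {}
    for name in ("LPA", "RPA"):
        p = head.fiducial_point(name)
        polys = mz.slice_plane(head.mesh, origin, normal)
        best = None
        for pts, _closed in polys:
            d = np.linalg.norm(pts[:, :2] - p[:2], axis=1)
            i = int(np.argmin(d))
            if best is None or d[i] < best[0]:
                best = (d[i], pts[i])
        out[f"{name}_cut"] = best[1]
    return out


def cut_panels(head: HeadMesh, landmarks: LandmarkSet,
               markers: dict[str, int] | None = None,
               axial_offset: float = 15.0,
               mid_fraction: float = 3.0 / 7.0,
               fraction_mode: str = "arc",
               optode_prefix: str = "optode:",
               snap_tol: float = 0.3) -> CutResult:
    """Cut the (embedded) head into left / mid / right panel surfaces.

    Vertices within `snap_tol` mm of a cut plane are absorbed into the cut
    line instead of being shaved off: this avoids needle triangles along the
    cuts (embedded 10-5 reference points deliberately sit very close to the
    sagittal planes), at the cost of the cut deviating from the exact plane
    by at most `snap_tol` where it passes through such a vertex.
    """
    markers = dict(markers or {})
    origin, normal = _axial_plane(head, axial_offset)
    x0 = sagittal_cut_offset(head, landmarks, mid_fraction, fraction_mode)

    (upper, prov_u), (lower, prov_l) = mz.split_with_plane(head.mesh, origin, normal,
                                                           eps=snap_tol)
    if len(upper.faces) == 0:
        raise GeometryError("axial cut removed the entire head")

    # remap markers through the cut; optodes must survive
    marker_pts = {k: head.mesh.vertices[v] for k, v in markers.items()}
    up_markers = _remap_markers(marker_pts, upper, prov_u, markers)
    for name in markers:
        if name.startswith(optode_prefix) and name not in up_markers:
            raise PlacementError(f"registered optode {name!r} falls below the axial cut")

    # sagittal splits: +x0 first (right), then -x0 (left vs mid)
    (right_m, prov_r), (rest_m, prov_rest) = mz.split_with_plane(
        upper, np.array([x0, 0, 0]), np.array([1.0, 0, 0]), eps=snap_tol)
    (mid_m, prov_m), (left_m, prov_left) = mz.split_with_plane(
        rest_m, np.array([-x0, 0, 0]), np.array([1.0, 0, 0]), eps=snap_tol)

    def compose(prov_stage, prov_parent):
        out = prov_stage.copy()
        ok = out >= 0
        out[ok] = prov_parent[out[ok]]
        return out

    panels = {}
    for role, (pm, prov_chain) in {
        "right": (right_m, compose(prov_r, prov_u)),
        "mid": (mid_m, compose(compose(prov_m, prov_rest), prov_u)),
        "left": (left_m, compose(compose(prov_left, prov_rest), prov_u)),
    }.items():
        vlabels, emap = _label_boundary(pm, origin, normal, x0, tol=snap_tol + PLANE_TOL)
        pmarkers = _remap_markers(marker_pts, pm, prov_chain, markers)
        panels[role] = PanelSurface(pm, prov_chain, role, vlabels, pmarkers, emap)

    total = head.mesh.area
    kept = sum(p.mesh.area for p in panels.values())
    return CutResult(panels, x0, total - kept, (origin, normal))


def _remap_markers(marker_pts, sub: TriMesh, prov: np.ndarray, orig_ids) -> dict[str, int]:
    """Marker vertex ids in a submesh, found via provenance (position fallback
    for markers duplicated onto cut lines)."""
    inv: dict[int, int] = {}
    for new, old in enumerate(prov):
        if old >= 0:
            inv[int(old)] = new
    out = {}
    for name, old in orig_ids.items():
        if int(old) in inv:
            out[name] = inv[int(old)]
        else:
            # vertex may coincide with a cut vertex
            d = np.linalg.norm(sub.vertices - marker_pts[name], axis=1)
            if len(d) and d.min() < 1e-6:
                out[name] = int(np.argmin(d))
    return out


def _label_boundary(pm: TriMesh, axial_origin, axial_normal, x0,
                    tol: float = PLANE_TOL):
    """Per-edge boundary labels (edge midpoints resolve corner ambiguity),
    plus derived per-vertex labels."""
    V = pm.vertices

    def classify(p):
        cands = [("sagittal-right", abs(p[0] - x0)),
                 ("sagittal-left", abs(p[0] + x0)),
                 ("axial", abs(float(np.dot(p - axial_origin, axial_normal))))]
        label, dist = min(cands, key=lambda kv: kv[1])
        return label if dist < tol else "rim"

    emap: dict[tuple[int, int], str] = {}
    vlabels: dict[int, str] = {}
    for a, b in pm.boundary_edges():
        a, b = int(a), int(b)
        label = classify(0.5 * (V[a] + V[b]))
        emap[(min(a, b), max(a, b))] = label
        for v in (a, b):
            prev = vlabels.get(v)
            if prev is None or (prev.startswith("sagittal") and label == "axial"):
                vlabels[v] = label
    return vlabels, emap
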
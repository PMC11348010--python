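"""Minimal triangle-mesh toolkit: containers, STL/OFF I/O, slicing and cutting.

Everything operates on plain numpy arrays; units are millimeters throughout.
The toolkit is intentionally small — only the primitives the cap pipeline
needs (plane slices for arc construction, half-space cuts for panelling,
exact point embedding and watertightness checks for emitted solids).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, GeometryError, TopologyError

_EPS = 1e-9


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Indexed triangle mesh.

    vertices : (n, 3) float64, mm
    faces    : (m, 3) int64, CCW seen from outside
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be (m, 3)")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise TopologyError("face references an out-of-range vertex")
        self._locator = None

    # -- basic derived quantities ------------------------------------------

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        t = self.triangles
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_normals(self) -> np.ndarray:
        c = self.face_cross()
        n = np.linalg.norm(c, axis=1)
        n[n == 0] = 1.0
        return c / n[:, None]

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    @property
    def volume(self) -> float:
        """Signed volume by the divergence theorem (positive for outward winding)."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def edges(self) -> np.ndarray:
        """All directed edges, (3m, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def unique_edges(self) -> np.ndarray:
        e = np.sort(self.edges(), axis=1)
        return np.unique(e, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one face, as directed (a, b) pairs."""
        e = self.edges()
        key = np.sort(e, axis=1)
        _, inv, cnt = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return e[cnt[inv] == 1]

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two faces, with opposite winding."""
        e = self.edges()
        key = np.sort(e, axis=1)
        uniq, inv, cnt = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        if not np.all(cnt == 2):
            return False
        # winding consistency: each undirected edge must appear once in each direction
        forward = e[:, 0] < e[:, 1]
        dirsum = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(dirsum, inv, np.where(forward, 1, -1))
        return bool(np.all(dirsum == 0))

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loops of the mesh boundary."""
        be = self.boundary_edges()
        nxt = {}
        for a, b in be:
            nxt[int(a)] = int(b)
        loops = []
        seen = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                if cur not in nxt:
                    raise TopologyError("open boundary chain (non-manifold boundary)")
                cur = nxt[cur]
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def connected_components(self) -> int:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.vertices)))
        g.add_edges_from(self.unique_edges().tolist())
        return nx.number_connected_components(g)

    # -- transforms --------------------------------------------------------

    def translated(self, t) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(t, dtype=float), self.faces.copy())

    def scaled(self, s: float) -> "TriMesh":
        return TriMesh(self.vertices * float(s), self.faces.copy())

    def transformed(self, rot: np.ndarray, t=(0.0, 0.0, 0.0)) -> "TriMesh":
        return TriMesh(self.vertices @ np.asarray(rot).T + np.asarray(t, dtype=float),
                       self.faces.copy())

    # -- proximity ---------------------------------------------------------

    def _get_locator(self) -> "_FaceLocator":
        if self._locator is None or self._locator.n_faces != len(self.faces):
            self._locator = _FaceLocator(self)
        return self._locator

    def closest_point(self, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest surface points for query points.

        Returns (points_on_surface, distances, face_indices).
        """
        return self._get_locator().query(np.atleast_2d(np.asarray(points, dtype=float)))

    # -- ray casting -------------------------------------------------------

    def ray_hits(self, origin, direction, eps: float = 1e-12) -> np.ndarray:
        """Parameters t of ray/triangle intersections (Moller-Trumbore), sorted."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        t = self.triangles
        e1 = t[:, 1] - t[:, 0]
        e2 = t[:, 2] - t[:, 0]
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - t[:, 0]
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = (q @ d) * inv
        tt = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (tt > eps)
        return np.sort(tt[hit])


class _FaceLocator:
    """Approximate-nearest-face index: centroid KD-tree + exact triangle distance."""

    def __init__(self, mesh: TriMesh, k: int = 32):
        self.mesh = mesh
        self.n_faces = len(mesh.faces)
        self.k = min(k, self.n_faces)
        self.tree = cKDTree(mesh.triangles.mean(axis=1))
        # conservative search radius pad: max circumradius proxy
        t = mesh.triangles
        self.pad = float(np.linalg.norm(t - t.mean(axis=1, keepdims=True), axis=2).max())

    def query(self, pts: np.ndarray):
        _, idx = self.tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        out_p = np.empty_like(pts)
        out_d = np.empty(len(pts))
        out_f = np.empty(len(pts), dtype=np.int64)
        tris = self.mesh.triangles
        for i, p in enumerate(pts):
            cand = idx[i]
            cp = _closest_point_triangles(p, tris[cand])
            d = np.linalg.norm(cp - p, axis=1)
            j = int(np.argmin(d))
            out_p[i], out_d[i], out_f[i] = cp[j], d[j], cand[j]
        return out_p, out_d, out_f


def _closest_point_triangles(p: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to p (Ericson, vectorized over triangles)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    out = np.empty_like(a)
    done = np.zeros(len(tris), dtype=bool)

    def assign(mask, val):
        m = mask & ~done
        out[m] = val[m] if val.ndim == 2 else val
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                      # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                     # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                     # vertex C
    vc = d1 * d4 - d3 * d2
    v = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v[:, None] * ab)   # edge AB
    vb = d5 * d2 - d1 * d6
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)   # edge AC
    va = d3 * d6 - d5 * d4
    w2 = np.divide(d4 - d3, (d4 - d3) + (d5 - d6),
                   out=np.zeros_like(d4), where=((d4 - d3) + (d5 - d6)) != 0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w2[:, None] * (c - b))  # edge BC
    denom = va + vb + vc
    denom[denom == 0] = 1.0
    v2 = (vb / denom)[:, None]
    w3 = (vc / denom)[:, None]
    assign(np.ones(len(tris), dtype=bool), a + ab * v2 + ac * w3)    # interior
    return out


# ---------------------------------------------------------------------------
# plane slicing (polylines) and half-space cutting
# ---------------------------------------------------------------------------


def plane_from_points(p0, p1, p2) -> tuple[np.ndarray, np.ndarray]:
    """(origin, unit normal) of the plane through three points."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    n = np.cross(p1 - p0, p2 - p0)
    ln = np.linalg.norm(n)
    if ln < 1e-12:
        raise GeometryError("degenerate plane: the three points are collinear")
    return p0, n / ln


def slice_plane(mesh: TriMesh, origin, normal, eps: float = 1e-9):
    """Intersect the surface with a plane.

    Returns a list of (points, closed) polylines. Vertices lying exactly on
    the plane are nudged to the positive side so the slice is a clean set of
    edge crossings (the polyline then passes within `eps` of such vertices).
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (mesh.vertices - origin) @ normal
    d = np.where(np.abs(d) < eps, eps, d)

    f = mesh.faces
    sd = d[f]
    crossing = ~((sd > 0).all(axis=1) | (sd < 0).all(axis=1))
    if not crossing.any():
        raise GeometryError("plane does not intersect the mesh")

    seg_pts = {}       # edge key -> intersection point
    seg_faces = []     # (keyA, keyB) per crossing face
    V = mesh.vertices
    for fi in np.nonzero(crossing)[0]:
        ids = f[fi]
        keys = []
        for a, b in ((ids[0], ids[1]), (ids[1], ids[2]), (ids[2], ids[0])):
            if d[a] * d[b] < 0:
                key = (min(a, b), max(a, b))
                if key not in seg_pts:
                    t = d[key[0]] / (d[key[0]] - d[key[1]])
                    seg_pts[key] = V[key[0]] + t * (V[key[1]] - V[key[0]])
                keys.append(key)
        if len(keys) == 2:
            seg_faces.append((keys[0], keys[1]))

    # chain segments: nodes are edge keys, links are faces
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(seg_faces)
    polylines = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ends = [n for n in sub if sub.degree(n) == 1]
        if ends:
            path = _walk_chain(sub, ends[0])
            closed = False
        else:
            start = next(iter(sub.nodes))
            path = _walk_chain(sub, start, closed=True)
            closed = True
        polylines.append((np.array([seg_pts[k] for k in path]), closed))
    return polylines


def _walk_chain(g, start, closed=False):
    path = [start]
    prev = None
    cur = start
    while True:
        nbrs = [n for n in g.neighbors(cur) if n != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
        if closed and cur == start:
            break
        path.append(cur)
    return path


def polyline_length(points: np.ndarray, closed: bool = False) -> float:
    p = np.asarray(points, dtype=float)
    L = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    if closed:
        L += float(np.linalg.norm(p[0] - p[-1]))
    return L


def split_with_plane(mesh: TriMesh, origin, normal, eps: float = 1e-7):
    """Split a mesh by a plane into (positive, negative) sides.

    Crossing triangles are retriangulated exactly along the plane; the new
    cut vertices are shared (identical coordinates) between the two halves.

    Returns two (TriMesh, provenance) pairs, where provenance maps each
    output vertex to its source vertex index, or -1 for a new cut vertex.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (mesh.vertices - origin) @ normal
    d = np.where(np.abs(d) < eps, 0.0, d)
    V = mesh.vertices

    new_pts: list[np.ndarray] = []
    cache: dict[tuple[int, int], int] = {}

    def cut_vertex(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            t = d[key[0]] / (d[key[0]] - d[key[1]])
            new_pts.append(V[key[0]] + t * (V[key[1]] - V[key[0]]))
            cache[key] = len(mesh.vertices) + len(new_pts) - 1
        return cache[key]

    pos_faces: list[tuple[int, int, int]] = []
    neg_faces: list[tuple[int, int, int]] = []
    for ids in mesh.faces:
        s = d[ids]
        if (s >= 0).all():
            if (s > 0).any():
                pos_faces.append(tuple(ids))
            continue
        if (s <= 0).all():
            neg_faces.append(tuple(ids))
            continue
        # clip into two polygons sharing the cut segment
        poly_p, poly_n = [], []
        for i in range(3):
            a, b = int(ids[i]), int(ids[(i + 1) % 3])
            if d[a] >= 0:
                poly_p.append(a)
            if d[a] <= 0:
                poly_n.append(a)
            if d[a] * d[b] < 0:
                c = cut_vertex(a, b)
                poly_p.append(c)
                poly_n.append(c)
        for poly, acc in ((poly_p, pos_faces), (poly_n, neg_faces)):
            for k in range(1, len(poly) - 1):
                acc.append((poly[0], poly[k], poly[k + 1]))

    all_v = np.vstack([V] + new_pts) if new_pts else V.copy()
    src = np.concatenate([np.arange(len(V)), -np.ones(len(new_pts), dtype=np.int64)])

    def compact(face_list):
        if not face_list:
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)), np.zeros(0, np.int64)
        faces = np.array(face_list, dtype=np.int64)
        used = np.unique(faces)
        remap = -np.ones(len(all_v), dtype=np.int64)
        remap[used] = np.arange(len(used))
        m = TriMesh(all_v[used], remap[faces])
        m = _drop_degenerate(m)
        return m, src[used]

    return compact(pos_faces), compact(neg_faces)


def _drop_degenerate(mesh: TriMesh, tol: float = 1e-12) -> TriMesh:
    keep = mesh.face_areas() > tol
    return TriMesh(mesh.vertices, mesh.faces[keep])


# ---------------------------------------------------------------------------
# exact point embedding
# ---------------------------------------------------------------------------


def embed_point(mesh: TriMesh, point, max_dist: float = 0.5,
                snap_tol: float = 0.05) -> tuple[TriMesh, int]:
    """Insert `point` as an exact mesh vertex.

    Coincident-with-vertex reuses the vertex; on-edge insertion splits the
    two incident faces (+1 vertex, +2 faces); interior insertion splits one
    face into three (+1 vertex, +2 faces). Total area is preserved because
    the inserted vertex lies on the face plane.
    """
    p = np.asarray(point, dtype=float)
    surf, dist, fi = mesh.closest_point(p[None])
    if dist[0] > max_dist:
        raise GeometryError(
            f"point {p.tolist()} is {dist[0]:.3f} mm from the surface (max {max_dist} mm)")
    q = surf[0]
    ids = mesh.faces[fi[0]]
    tri = mesh.vertices[ids]

    # vertex snap
    dv = np.linalg.norm(tri - q, axis=1)
    if dv.min() < snap_tol:
        return mesh, int(ids[int(np.argmin(dv))])

    # edge snap: insert the exact on-edge projection so area is unchanged
    for k in range(3):
        a, b = tri[k], tri[(k + 1) % 3]
        ab = b - a
        t = np.clip(np.dot(q - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        q_edge = a + t * ab
        if np.linalg.norm(q_edge - q) < snap_tol:
            ia, ib = int(ids[k]), int(ids[(k + 1) % 3])
            return _split_edge(mesh, ia, ib, q_edge)

    # interior split: face (a,b,c) -> (a,b,q), (b,c,q), (c,a,q)
    nv = len(mesh.vertices)
    V = np.vstack([mesh.vertices, q[None]])
    a, b, c = (int(x) for x in ids)
    keep = np.delete(mesh.faces, fi[0], axis=0)
    F = np.vstack([keep, [[a, b, nv], [b, c, nv], [c, a, nv]]])
    return TriMesh(V, F), nv


def _split_edge(mesh: TriMesh, ia: int, ib: int, q: np.ndarray) -> tuple[TriMesh, int]:
    nv = len(mesh.vertices)
    V = np.vstack([mesh.vertices, q[None]])
    F = mesh.faces
    has = ((F == ia).any(axis=1)) & ((F == ib).any(axis=1))
    inc = np.nonzero(has)[0]
    new_faces = []
    for fi in inc:
        tri = [int(x) for x in F[fi]]
        # replace edge (ia, ib) with (ia, nv) and (nv, ib) preserving winding
        out1 = [nv if v == ib else v for v in tri]
        out2 = [nv if v == ia else v for v in tri]
        new_faces.extend([out1, out2])
    keep = np.delete(F, inc, axis=0)
    F2 = np.vstack([keep, np.array(new_faces, dtype=np.int64)])
    m = _drop_degenerate(TriMesh(V, F2))
    return m, nv


# ---------------------------------------------------------------------------
# STL / OFF I/O
# ---------------------------------------------------------------------------


def write_stl(mesh: TriMesh, path, mode: str = "binary", name: str = "capgen") -> None:
    tris = mesh.triangles.astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if mode == "binary":
        with open(path, "wb") as fh:
            fh.write(name.encode().ljust(80, b"\0")[:80])
            fh.write(struct.pack("<I", len(tris)))
            rec = np.zeros(len(tris), dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                             ("attr", "<u2")])
            rec["n"] = normals
            rec["v"] = tris
            fh.write(rec.tobytes())
    elif mode == "ascii":
        with open(path, "w") as fh:
            fh.write(f"solid {name}\n")
            for n, t in zip(normals, tris):
                fh.write(f"facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n outer loop\n")
                for v in t:
                    fh.write(f"  vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write(f"endsolid {name}\n")
    else:
        raise FormatError(f"unknown STL mode {mode!r}")


def read_stl(path) -> TriMesh:
    with open(path, "rb") as fh:
        head = fh.read(80)
        rest = fh.read()
    if _looks_ascii_stl(head, rest):
        return _parse_ascii_stl((head + rest).decode(errors="replace"))
    (n,) = struct.unpack_from("<I", rest, 0)
    rec = np.frombuffer(rest, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
                        count=n, offset=4)
    return _mesh_from_soup(rec["v"].astype(np.float64).reshape(-1, 3))


def _looks_ascii_stl(head: bytes, rest: bytes) -> bool:
    if not head.lstrip().startswith(b"solid"):
        return False
    try:
        (n,) = struct.unpack_from("<I", rest, 0)
        if len(rest) == 4 + 50 * n:
            return False  # valid binary payload despite "solid" header
    except struct.error:
        pass
    return b"facet" in rest[:2048] or b"facet" in head


def _parse_ascii_stl(text: str) -> TriMesh:
    pts = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            pts.append([float(x) for x in line.split()[1:4]])
    if len(pts) % 3:
        raise FormatError("ASCII STL vertex count not a multiple of 3")
    return _mesh_from_soup(np.array(pts, dtype=np.float64))


def _mesh_from_soup(flat: np.ndarray, tol: float = 1e-6) -> TriMesh:
    """Weld a triangle soup (3k, 3) into an indexed mesh."""
    key = np.round(flat / tol).astype(np.int64)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return TriMesh(flat[idx], inv.reshape(-1, 3))


def write_off(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_off(path) -> TriMesh:
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    i = 4
    verts = np.array(tokens[i:i + 3 * nv], dtype=float).reshape(nv, 3)
    i += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[i])
        if k != 3:
            raise FormatError("only triangular OFF faces are supported")
        faces.append([int(tokens[i + 1]), int(tokens[i + 2]), int(tokens[i + 3])])
        i += k + 1
    return TriMesh(verts, np.array(faces, dtype=np.int64))
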
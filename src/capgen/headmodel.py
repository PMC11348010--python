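"""Scalp mesh model: synthetic heads, arc measurements, 10-5 landmarks, scaling.

Coordinate convention (mm): +X toward RPA, +Y toward Nz, +Z superior; the
Iz-Cz-Nz midline lies in the X = 0 plane for the synthetic heads.

All landmark arcs are planar slices of the scalp surface: the midline arc is
cut by the plane through Nz, Iz and Cz, the central coronal arc by the plane
through LPA, RPA and Cz, and so on for the intermediate chains. Cz itself is
found by alternating the two arc-midpoint constraints until it moves by less
than 0.1 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import mesh as mz
from .errors import GeometryError, InvalidFiducialError, InvalidParameterError
from .mesh import TriMesh

FIDUCIAL_NAMES = ("Nz", "Iz", "LPA", "RPA")

#: Midline arc labels, Nz -> Iz, at 5% arc-length increments.
MIDLINE_LABELS = (
    "Nz", "NFpz", "Fpz", "AFpz", "AFz", "AFFz", "Fz", "FFCz", "FCz", "FCCz",
    "Cz", "CCPz", "CPz", "CPPz", "Pz", "PPOz", "POz", "POOz", "Oz", "OIz", "Iz",
)

#: Central coronal arc labels, LPA -> RPA, at 5% arc-length increments.
CORONAL_LABELS = (
    "LPA", "T9h", "T7", "T7h", "C5", "C5h", "C3", "C3h", "C1", "C1h",
    "Cz", "C2h", "C2", "C4h", "C4", "C6h", "C6", "T8h", "T8", "T10h", "RPA",
)

# Intermediate coronal chains: (left end, midline point, right end,
# left-half labels at 25/50/75%, right-half labels at 25/50/75%).
# The second block is the 5%-level ("h") rows of the 10-5 grid, anchored at
# the odd-fraction ring points.
_ROW_CHAINS = (
    ("AF7", "AFz", "AF8", ("AF5", "AF3", "AF1"), ("AF2", "AF4", "AF6")),
    ("F7", "Fz", "F8", ("F5", "F3", "F1"), ("F2", "F4", "F6")),
    ("FT7", "FCz", "FT8", ("FC5", "FC3", "FC1"), ("FC2", "FC4", "FC6")),
    ("TP7", "CPz", "TP8", ("CP5", "CP3", "CP1"), ("CP2", "CP4", "CP6")),
    ("P7", "Pz", "P8", ("P5", "P3", "P1"), ("P2", "P4", "P6")),
    ("PO7", "POz", "PO8", ("PO5", "PO3", "PO1"), ("PO2", "PO4", "PO6")),
    ("AFp7", "AFpz", "AFp8", ("AFp5", "AFp3", "AFp1"), ("AFp2", "AFp4", "AFp6")),
    ("AFF7", "AFFz", "AFF8", ("AFF5", "AFF3", "AFF1"), ("AFF2", "AFF4", "AFF6")),
    ("FFT7", "FFCz", "FFT8", ("FFC5", "FFC3", "FFC1"), ("FFC2", "FFC4", "FFC6")),
    ("FTT7", "FCCz", "FTT8", ("FCC5", "FCC3", "FCC1"), ("FCC2", "FCC4", "FCC6")),
    ("TTP7", "CCPz", "TTP8", ("CCP5", "CCP3", "CCP1"), ("CCP2", "CCP4", "CCP6")),
    ("TPP7", "CPPz", "TPP8", ("CPP5", "CPP3", "CPP1"), ("CPP2", "CPP4", "CPP6")),
    ("PPO7", "PPOz", "PPO8", ("PPO5", "PPO3", "PPO1"), ("PPO2", "PPO4", "PPO6")),
    ("POO7", "POOz", "POO8", ("POO5", "POO3", "POO1"), ("POO2", "POO4", "POO6")),
)


@dataclass
class HeadMesh:
    """Triangulated scalp surface with named fiducial vertices."""

    mesh: TriMesh
    fiducials: dict[str, int]

    def __post_init__(self):
        missing = [k for k in FIDUCIAL_NAMES if k not in self.fiducials]
        if missing:
            raise InvalidFiducialError(f"missing fiducials: {missing}")

    def fiducial_point(self, name: str) -> np.ndarray:
        return self.mesh.vertices[self.fiducials[name]]

    @property
    def fiducial_points(self) -> dict[str, np.ndarray]:
        return {k: self.fiducial_point(k) for k in self.fiducials}

    def copy(self) -> "HeadMesh":
        return HeadMesh(self.mesh.copy(), dict(self.fiducials))


@dataclass
class LandmarkSet:
    """Named 10-5 positions: surface points, plus vertex ids once embedded."""

    positions: dict[str, np.ndarray]
    vertex_ids: dict[str, int] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return list(self.positions)

    def point(self, label: str) -> np.ndarray:
        return self.positions[label]

    def scaled(self, factor: float) -> "LandmarkSet":
        return LandmarkSet({k: v * factor for k, v in self.positions.items()},
                           dict(self.vertex_ids))

    def to_json(self) -> str:
        return json.dumps({k: [float(x) for x in v] for k, v in self.positions.items()},
                          indent=1)


# ---------------------------------------------------------------------------
# synthetic head
# ---------------------------------------------------------------------------


def generate_synthetic_head(circumference_cm: float,
                            axis_ratios=(1.0, 1.0, 1.0),
                            refinement: int = 3,
                            skirt_depth: float = 25.0,
                            n_skirt: int = 2) -> HeadMesh:
    """Upper-half ellipsoid head with a short vertical skirt below the rim.

    The rim (z = 0) ring passes through the four fiducials Nz (+Y), Iz (-Y),
    LPA (-X), RPA (+X) and its polygonal circumference equals the requested
    head circumference. `axis_ratios` scale the (X, Y, Z) semi-axes; the
    skirt extends `skirt_depth` mm straight down from the rim so the axial
    panel cut has material to discard.
    """
    a, b, c = (float(x) for x in axis_ratios)
    if min(a, b, c) <= 0:
        raise InvalidParameterError("axis ratios must be positive")
    if circumference_cm <= 0:
        raise InvalidParameterError("circumference must be positive")
    if refinement < 2:
        raise InvalidParameterError("refinement must be >= 2")

    # octahedron-based hemisphere: near-uniform triangle quality (a lat-long
    # grid's polar fan develops a zero-energy swirl under spring flattening),
    # exact vertices on the rim at the four compass points, pole degree 4.
    uv, uf = _octasphere_upper(refinement)
    n_lon = 4 * 2 ** refinement

    # unit rim polygon perimeter fixes the base radius exactly
    phi = 2 * np.pi * np.arange(n_lon) / n_lon
    rim = np.stack([a * np.cos(phi), b * np.sin(phi)], axis=1)
    per_unit = float(np.linalg.norm(np.diff(np.vstack([rim, rim[:1]]), axis=0), axis=1).sum())
    r = circumference_cm * 10.0 / per_unit

    V = np.column_stack([r * a * uv[:, 0], r * b * uv[:, 1], r * c * uv[:, 2]])
    faces = [list(f) for f in uf]

    # rim ring ordered by azimuth, used to attach the skirt
    rim_ids = np.nonzero(np.abs(uv[:, 2]) < 1e-12)[0]
    order = np.argsort(np.arctan2(uv[rim_ids, 1], uv[rim_ids, 0]) % (2 * np.pi))
    rim_ids = rim_ids[order]
    nr = len(rim_ids)
    prev_ring = list(rim_ids)
    for i in range(1, n_skirt + 1):
        z = -skirt_depth * i / n_skirt
        ring = []
        for vid in rim_ids:
            ring.append(len(V))
            V = np.vstack([V, [V[vid, 0], V[vid, 1], z]])
        for k in range(nr):
            k2 = (k + 1) % nr
            lo, lo2 = ring[k], ring[k2]
            hi, hi2 = prev_ring[k], prev_ring[k2]
            faces.append([lo, lo2, hi2])
            faces.append([lo, hi2, hi])
        prev_ring = ring

    def rim_at(angle):
        target = np.array([np.cos(angle), np.sin(angle)])
        d = np.linalg.norm(uv[rim_ids][:, :2] - target, axis=1)
        return int(rim_ids[int(np.argmin(d))])

    fiducials = {"RPA": rim_at(0.0), "Nz": rim_at(np.pi / 2),
                 "LPA": rim_at(np.pi), "Iz": rim_at(3 * np.pi / 2)}
    return HeadMesh(TriMesh(V, np.array(faces, dtype=np.int64)), fiducials)


def _octasphere_upper(refinement: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper half of a unit sphere from octahedron subdivision.

    Midpoint-subdivide the four upper octahedron faces `refinement` times,
    normalizing onto the sphere. Equatorial edges stay exactly on z = 0, so
    the rim is a clean vertex ring with 4 * 2**refinement points.
    """
    verts = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([-1.0, 0, 0]),
             np.array([0, -1.0, 0]), np.array([0, 0, 1.0])]
    faces = [(0, 1, 4), (1, 2, 4), (2, 3, 4), (3, 0, 4)]
    for _ in range(refinement):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                m = m / np.linalg.norm(m)
                if abs(m[2]) < 1e-15:
                    m[2] = 0.0
                cache[key] = len(verts)
                verts.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts), np.array(faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# arcs
# ---------------------------------------------------------------------------


def _project_to_polyline(points: np.ndarray, p: np.ndarray):
    """(segment index, parameter, closest point, distance) on an open polyline."""
    a = points[:-1]
    d = points[1:] - a
    L2 = np.einsum("ij,ij->i", d, d)
    L2[L2 == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / L2, 0.0, 1.0)
    q = a + t[:, None] * d
    dist = np.linalg.norm(q - p, axis=1)
    i = int(np.argmin(dist))
    return i, float(t[i]), q[i], float(dist[i])


def slice_arc(mesh: TriMesh, plane_points, a, b, via=None, prefer: str = "top",
              on_curve_tol: float = 2.0) -> np.ndarray:
    """Polyline from `a` to `b` along the plane/surface intersection curve.

    For a closed intersection loop the branch is chosen to contain `via`
    when given, otherwise by `prefer`: "top" takes the branch reaching the
    larger Z (over the head), "short" the shorter branch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    origin, normal = mz.plane_from_points(*plane_points)
    polylines = mz.slice_plane(mesh, origin, normal)

    best = None
    for pts, closed in polylines:
        loop = np.vstack([pts, pts[:1]]) if closed else pts
        _, _, _, da = _project_to_polyline(loop, a)
        _, _, _, db = _project_to_polyline(loop, b)
        score = da + db
        if best is None or score < best[0]:
            best = (score, pts, closed, da, db)
    _, pts, closed, da, db = best
    if da > on_curve_tol or db > on_curve_tol:
        raise GeometryError(
            f"arc endpoints are {da:.2f}/{db:.2f} mm off the slice curve")

    loop = np.vstack([pts, pts[:1]]) if closed else pts
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    ia, ta, qa, _ = _project_to_polyline(loop, a)
    ib, tb, qb, _ = _project_to_polyline(loop, b)
    sa = cum[ia] + ta * seg[ia]
    sb = cum[ib] + tb * seg[ib]

    def extract(s0, q0, s1, q1):
        """Forward walk from arclength s0 to s1 (wrapping if closed)."""
        if closed and s1 <= s0:
            s1 += total
        m = len(loop) - 1  # segment count; loop[m] == loop[0] on closed loops
        idx = []
        for j in range(1, 2 * m if closed else m):
            sv = cum[j] if j <= m else cum[j - m] + total
            if s0 + 1e-12 < sv < s1 - 1e-12:
                idx.append(j % m)
            elif sv >= s1:
                break
        return np.array([q0] + [loop[i] for i in idx] + [q1])

    if not closed:
        if sa <= sb:
            arc = extract(sa, qa, sb, qb)
        else:
            arc = extract(sb, qb, sa, qa)[::-1]
        return _dedupe(arc)

    fwd = _dedupe(extract(sa, qa, sb, qb))
    bwd = _dedupe(extract(sb, qb, sa, qa))[::-1]
    if via is not None:
        via = np.asarray(via, dtype=float)
        dfwd = _project_to_polyline(fwd, via)[3] if len(fwd) > 1 else np.inf
        dbwd = _project_to_polyline(bwd, via)[3] if len(bwd) > 1 else np.inf
        return fwd if dfwd <= dbwd else bwd
    if prefer == "top":
        return fwd if fwd[:, 2].max() >= bwd[:, 2].max() else bwd
    lf = mz.polyline_length(fwd)
    lb = mz.polyline_length(bwd)
    return fwd if lf <= lb else bwd


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    if len(points) < 2:
        return points
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


def arc_length(mesh: TriMesh, a, b, plane_points, via=None, prefer: str = "top") -> float:
    """Length (mm) of the plane-slice arc from a to b over the surface."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.linalg.norm(a - b) < 1e-12:
        return 0.0
    return mz.polyline_length(slice_arc(mesh, plane_points, a, b, via=via, prefer=prefer))


def subdivide_arc(points: np.ndarray, fractions) -> np.ndarray:
    """Points at the given arc-length fractions (0..1) along a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise GeometryError("cannot subdivide a zero-length arc")
    out = []
    for f in np.atleast_1d(fractions):
        s = float(f) * total
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out.append(points[i] + t * (points[i + 1] - points[i]))
    return np.array(out)


# ---------------------------------------------------------------------------
# circumference and scaling
# ---------------------------------------------------------------------------


def measure_circumference(head: HeadMesh) -> float:
    """Closed-loop circumference (mm) through Nz-LPA-Iz-RPA."""
    fp = head.fiducial_points
    origin, normal = _fiducial_plane(fp)
    polylines = mz.slice_plane(head.mesh, origin, normal)
    best = None
    for pts, closed in polylines:
        if not closed:
            continue
        loop = np.vstack([pts, pts[:1]])
        score = sum(_project_to_polyline(loop, fp[k])[3] for k in FIDUCIAL_NAMES)
        if best is None or score < best[0]:
            best = (score, pts)
    if best is None:
        raise GeometryError("no closed circumference loop through the fiducial plane")
    return mz.polyline_length(best[1], closed=True)


def _fiducial_plane(fp: dict[str, np.ndarray]):
    pts = np.array([fp[k] for k in FIDUCIAL_NAMES])
    if min(np.linalg.norm(pts[i] - pts[j]) for i in range(4) for j in range(i + 1, 4)) < 1e-6:
        raise InvalidFiducialError("coincident fiducials")
    centroid = pts.mean(axis=0)
    _, s, vh = np.linalg.svd(pts - centroid)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise InvalidFiducialError("collinear fiducials")
    return centroid, vh[2]


def scale_head(head: HeadMesh, landmarks: LandmarkSet | None,
               target_hc_cm: float) -> tuple[HeadMesh, LandmarkSet | None]:
    """Scale every coordinate by target_HC / current_HC about the origin."""
    if target_hc_cm <= 0:
        raise InvalidParameterError("target head circumference must be positive")
    current = measure_circumference(head)
    if current <= 0:
        raise GeometryError("current head circumference is unmeasurable")
    f = target_hc_cm * 10.0 / current
    scaled = HeadMesh(head.mesh.scaled(f), dict(head.fiducials))
    return scaled, (landmarks.scaled(f) if landmarks is not None else None)


# ---------------------------------------------------------------------------
# 10-5 landmark construction
# ---------------------------------------------------------------------------


def compute_10_5_landmarks(head: HeadMesh, cz_tol: float = 0.1,
                           max_iter: int = 60) -> LandmarkSet:
    """Build the 10-5 landmark grid by iterative planar arc subdivision.

    Principal (midline, central coronal) arcs carry the full 5% grid; the
    lateral 10-10 grid is added via the circumferential ring through
    Fpz/T7/Oz and intermediate coronal chains. Anterior/posterior rim
    reference points (NFp1/2, NFp1h/2h, I1/2, I1h/2h) are placed on the
    fiducial-plane rim ring at 20%/40% of each rim quadrant.
    """
    mesh = head.mesh
    fp = head.fiducial_points
    nz, iz, lpa, rpa = fp["Nz"], fp["Iz"], fp["LPA"], fp["RPA"]
    _fiducial_plane(fp)  # raises on degenerate fiducials

    # --- Cz by alternating arc midpoints --------------------------------
    cz = mesh.vertices[np.argmax(mesh.vertices[:, 2])].copy()
    for _ in range(max_iter):
        mid_arc = slice_arc(mesh, (nz, iz, cz), nz, iz, via=cz)
        m1 = subdivide_arc(mid_arc, [0.5])[0]
        cor_arc = slice_arc(mesh, (lpa, rpa, m1), lpa, rpa, via=m1)
        m2 = subdivide_arc(cor_arc, [0.5])[0]
        if np.linalg.norm(m2 - cz) < cz_tol:
            cz = m2
            break
        cz = m2
    else:
        raise GeometryError("Cz fixed-point iteration did not converge")

    pos: dict[str, np.ndarray] = {}

    mid_arc = slice_arc(mesh, (nz, iz, cz), nz, iz, via=cz)
    for label, p in zip(MIDLINE_LABELS, subdivide_arc(mid_arc, np.linspace(0, 1, 21))):
        pos[label] = p
    cor_arc = slice_arc(mesh, (lpa, rpa, cz), lpa, rpa, via=cz)
    for label, p in zip(CORONAL_LABELS, subdivide_arc(cor_arc, np.linspace(0, 1, 21))):
        pos[label] = p
    pos["Nz"], pos["Iz"], pos["LPA"], pos["RPA"] = nz, iz, lpa, rpa
    pos["Cz"] = cz

    # --- rim reference points on the fiducial-plane ring ----------------
    # Four anchors are generally not coplanar: slice along their best-fit
    # plane and subdivide the loop between the anchor projections.
    rim_quadrants = (
        ("Nz", "LPA", ("NFp1h", "NFp1"), (0.2, 0.4)),
        ("Nz", "RPA", ("NFp2h", "NFp2"), (0.2, 0.4)),
        ("Iz", "LPA", ("I1h", "I1"), (0.2, 0.4)),
        ("Iz", "RPA", ("I2h", "I2"), (0.2, 0.4)),
    )
    _ring_labels(mesh, pos, ("Nz", "LPA", "Iz", "RPA"), rim_quadrants)

    # --- circumferential ring through Fpz / T7 / Oz / T8 ----------------
    frac9 = tuple(0.1 * k for k in range(1, 10))
    ring_quadrants = (
        ("Fpz", "T7",
         ("Fp1h", "Fp1", "AFp7", "AF7", "AFF7", "F7", "FFT7", "FT7", "FTT7"), frac9),
        ("Fpz", "T8",
         ("Fp2h", "Fp2", "AFp8", "AF8", "AFF8", "F8", "FFT8", "FT8", "FTT8"), frac9),
        ("Oz", "T7",
         ("O1h", "O1", "POO7", "PO7", "PPO7", "P7", "TPP7", "TP7", "TTP7"), frac9),
        ("Oz", "T8",
         ("O2h", "O2", "POO8", "PO8", "PPO8", "P8", "TPP8", "TP8", "TTP8"), frac9),
    )
    _ring_labels(mesh, pos, ("Fpz", "T7", "Oz", "T8"), ring_quadrants)

    # --- intermediate coronal chains ------------------------------------
    for left, midp, right, lnames, rnames in _ROW_CHAINS:
        larc = slice_arc(mesh, (pos[left], pos[midp], pos[right]),
                         pos[left], pos[midp], prefer="short")
        rarc = slice_arc(mesh, (pos[left], pos[midp], pos[right]),
                         pos[midp], pos[right], prefer="short")
        for label, p in zip(lnames, subdivide_arc(larc, [0.25, 0.5, 0.75])):
            pos[label] = p
        for label, p in zip(rnames, subdivide_arc(rarc, [0.25, 0.5, 0.75])):
            pos[label] = p

    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in pos.items()})


def _ring_labels(mesh: TriMesh, pos: dict, anchor_labels, quadrants) -> None:
    """Place labels on the closed ring through four anchors (best-fit plane).

    Each quadrant entry is (anchor A, anchor B, labels, fractions): labels go
    at the given arc-length fractions of the A->B loop sub-arc that avoids
    the other two anchors.
    """
    anchors = {k: np.asarray(pos[k], dtype=float) for k in anchor_labels}
    pts = np.array(list(anchors.values()))
    centroid = pts.mean(axis=0)
    normal = np.linalg.svd(pts - centroid)[2][2]
    polylines = mz.slice_plane(mesh, centroid, normal)
    best = None
    for cand, closed in polylines:
        if not closed:
            continue
        loop = np.vstack([cand, cand[:1]])
        score = sum(_project_to_polyline(loop, p)[3] for p in anchors.values())
        if best is None or score < best[0]:
            best = (score, cand)
    if best is None:
        raise GeometryError("ring slice produced no closed loop")
    loop = np.vstack([best[1], best[1][:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]

    def param(p):
        i, t, q, _ = _project_to_polyline(loop, p)
        return cum[i] + t * seg[i], q

    sp = {k: param(p) for k, p in anchors.items()}

    def subarc(sa, sb, excluded):
        """Polyline a->b, choosing the loop direction avoiding `excluded`."""
        def walk(s0, s1):
            if s1 <= s0:
                s1 += total
            inside = [s for s in excluded
                      if s0 + 1e-9 < s < s1 - 1e-9 or s0 + 1e-9 < s + total < s1 - 1e-9]
            pts_ = [sp_interp(s0)]
            j = int(np.searchsorted(cum, s0, side="right"))
            while cum[j % (len(cum) - 1)] + (total if j >= len(cum) - 1 else 0) < s1 - 1e-9:
                pts_.append(loop[j % (len(loop) - 1)])
                j += 1
                if j > 2 * len(loop):
                    break
            pts_.append(sp_interp(s1 % total))
            return np.array(pts_), len(inside) == 0

        fwd, ok_f = walk(sa, sb)
        if ok_f:
            return fwd
        bwd, ok_b = walk(sb, sa)
        if ok_b:
            return bwd[::-1]
        return fwd  # degenerate; should not happen with 4 distinct anchors

    def sp_interp(s):
        s = s % total
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(max(i, 0), len(seg) - 1)
        t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        return loop[i] + t * (loop[i + 1] - loop[i])

    for a_lbl, b_lbl, labels, fracs in quadrants:
        others = [sp[k][0] for k in anchors if k not in (a_lbl, b_lbl)]
        arc = _dedupe(subarc(sp[a_lbl][0], sp[b_lbl][0], others))
        for label, p in zip(labels, subdivide_arc(arc, list(fracs))):
            pos[label] = p


# ---------------------------------------------------------------------------
# fiducial sidecar I/O
# ---------------------------------------------------------------------------


def write_fiducials_json(head: HeadMesh, path) -> None:
    data = {k: [float(x) for x in head.fiducial_point(k)] for k in head.fiducials}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_head(mesh_path, fiducials_path) -> HeadMesh:
    """Load a scalp mesh (STL or OFF) plus a {label: [x,y,z]} JSON sidecar."""
    p = str(mesh_path)
    m = mz.read_off(p) if p.lower().endswith(".off") else mz.read_stl(p)
    with open(fiducials_path) as fh:
        pts = json.load(fh)
    fid = {}
    for name in FIDUCIAL_NAMES:
        if name not in pts:
            raise InvalidFiducialError(f"fiducial sidecar is missing {name}")
        d = np.linalg.norm(m.vertices - np.asarray(pts[name], dtype=float), axis=1)
        idx = int(np.argmin(d))
        if d[idx] > 2.0:
            raise InvalidFiducialError(
                f"fiducial {name} is {d[idx]:.2f} mm from the nearest mesh vertex")
        fid[name] = idx
    return HeadMesh(m, fid)
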
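"""Ear-clipping triangulation for polygons with holes.

Holes are spliced into the outer ring via horizontal-ray bridges with the
visibility correction, then the simple polygon is clipped ear by ear.

All geometric predicates run in a frame rotated by an irrational angle:
grid-aligned inputs (hex lattices) are full of exactly-collinear and
exactly-on-ray configurations that break the classic algorithm, and a fixed
rotation removes them without perturbing the output coordinates (triangles
are emitted as indices into the untouched input vertices).

Degenerate (collinear) ears are emitted as zero-area triangles so the edge
structure of stacked solids stays closed.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

_ROT_ANGLE = 0.3812986218374  # irrational-ish; breaks axis-aligned degeneracies
_COS, _SIN = float(np.cos(_ROT_ANGLE)), float(np.sin(_ROT_ANGLE))


def ring_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ensure_orientation(pts: np.ndarray, ccw: bool) -> np.ndarray:
    a = ring_area(pts)
    if (a > 0) != ccw and abs(a) > 0:
        return pts[::-1].copy()
    return pts


def _dedup_ring(pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    while len(keep) > 1 and np.linalg.norm(pts[keep[-1]] - pts[keep[0]]) <= tol:
        keep.pop()
    return pts[keep]


def _point_in_tri(q, a, b, c, eps: float = 1e-12) -> bool:
    d1 = (q[0] - a[0]) * (b[1] - a[1]) - (q[1] - a[1]) * (b[0] - a[0])
    d2 = (q[0] - b[0]) * (c[1] - b[1]) - (q[1] - b[1]) * (c[0] - b[0])
    d3 = (q[0] - c[0]) * (a[1] - c[1]) - (q[1] - c[1]) * (a[0] - c[0])
    neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (neg and pos)


def _bridge_hole(outer: list[int], hole: list[int], W: np.ndarray) -> list[int]:
    """Splice `hole` (CW index ring) into `outer` (CCW index ring).

    `W` holds the working (rotated) coordinates for all indices.
    """
    hi = int(np.argmax([W[i][0] for i in hole]))
    M = W[hole[hi]]
    n = len(outer)

    best = None  # (x_intersection, edge_index)
    for i in range(n):
        p1, p2 = W[outer[i]], W[outer[(i + 1) % n]]
        y1, y2 = p1[1] - M[1], p2[1] - M[1]
        if (y1 > 0 and y2 > 0) or (y1 < 0 and y2 < 0):
            continue
        dy = p2[1] - p1[1]
        if abs(dy) < 1e-15:
            cands = [p[0] for p in (p1, p2) if p[0] >= M[0] - 1e-12]
            if not cands:
                continue
            x = min(cands)
        else:
            t = (M[1] - p1[1]) / dy
            if not -1e-12 <= t <= 1 + 1e-12:
                continue
            x = p1[0] + t * (p2[0] - p1[0])
        if x >= M[0] - 1e-12 and (best is None or x < best[0]):
            best = (x, i)
    if best is None:
        raise GeometryError("hole bridge failed: hole not inside outer ring")
    xI, ei = best
    I = np.array([xI, M[1]])
    p1, p2 = W[outer[ei]], W[outer[(ei + 1) % n]]
    c = ei if p1[0] > p2[0] else (ei + 1) % n       # endpoint with larger x
    P = W[outer[c]]

    # visibility: vertices inside triangle (M, I, P) redirect the bridge to
    # the one minimizing the angle with the ray (then distance)
    blockers = []
    for j in range(n):
        if j == c:
            continue
        q = W[outer[j]]
        if q[0] < M[0] - 1e-12 or q[0] > max(xI, P[0]) + 1e-12:
            continue
        if np.allclose(q, P) or np.allclose(q, M):
            continue
        if _point_in_tri(q, M, I, P):
            dx = q[0] - M[0]
            tan = abs(q[1] - M[1]) / max(dx, 1e-12)
            blockers.append((tan, dx, j))
    if blockers:
        blockers.sort()
        c = blockers[0][2]

    rotated = [hole[(hi + k) % len(hole)] for k in range(len(hole))]
    return outer[:c + 1] + rotated + [hole[hi], outer[c]] + outer[c + 1:]


def triangulate_polygon(exterior: np.ndarray,
                        holes: list[np.ndarray] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a polygon with holes.

    Returns (vertices (N, 2), triangles (M, 3) indices, CCW winding). The
    output vertices are exactly the input ring vertices (exterior first,
    then holes, deduplicated per ring).
    """
    ext = _dedup_ring(_ensure_orientation(np.asarray(exterior, dtype=float), ccw=True))
    if len(ext) < 3:
        raise GeometryError("degenerate exterior ring")
    rings = [ext]
    for h in holes or []:
        h = _dedup_ring(_ensure_orientation(np.asarray(h, dtype=float), ccw=False))
        if len(h) >= 3:
            rings.append(h)

    verts = np.vstack(rings)
    # working coordinates: rotated frame (breaks grid-aligned degeneracies)
    W = np.column_stack([verts[:, 0] * _COS - verts[:, 1] * _SIN,
                         verts[:, 0] * _SIN + verts[:, 1] * _COS])

    offsets = np.cumsum([0] + [len(r) for r in rings])
    outer = list(range(offsets[0], offsets[1]))
    hole_rings = [list(range(offsets[k], offsets[k + 1])) for k in range(1, len(rings))]
    for hr in sorted(hole_rings, key=lambda hr: -float(np.max(W[hr, 0]))):
        outer = _bridge_hole(outer, hr, W)

    idx = list(outer)
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    guard = 0
    max_guard = 4 * len(idx) * len(idx) + 64
    while len(idx) > 3:
        guard += 1
        if guard > max_guard:
            raise GeometryError("ear clipping stalled (self-intersecting outline?)")
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = W[i0], W[i1], W[i2]
            cr = cross(a, b, c)
            if cr < -1e-12:
                continue  # reflex
            if cr <= 1e-12:
                # collinear ear: zero-area triangle keeps edges paired
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
            others = np.array([W[j] for j in idx if j not in (i0, i1, i2)])
            if len(others) and _any_in_triangle(others, a, b, c):
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # numerical dead end: clip the most convex corner to make progress
            worst = max(range(m), key=lambda k: cross(W[idx[(k - 1) % m]],
                                                      W[idx[k]],
                                                      W[idx[(k + 1) % m]]))
            k = worst
            tris.append((idx[(k - 1) % m], idx[k], idx[(k + 1) % m]))
            idx.pop(k)
    tris.append((idx[0], idx[1], idx[2]))
    return verts, np.array(tris, dtype=np.int64)


def _any_in_triangle(pts: np.ndarray, a, b, c) -> bool:
    d1 = (pts[:, 0] - a[0]) * (b[1] - a[1]) - (pts[:, 1] - a[1]) * (b[0] - a[0])
    d2 = (pts[:, 0] - b[0]) * (c[1] - b[1]) - (pts[:, 1] - b[1]) * (c[0] - b[0])
    d3 = (pts[:, 0] - c[0]) * (a[1] - c[1]) - (pts[:, 1] - c[1]) * (a[0] - c[0])
    eps = -1e-12
    # (p-a) x (b-a) ordering: interior of a CCW triangle is all-negative
    return bool(np.any((d1 < eps) & (d2 < eps) & (d3 < eps)))
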
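"""Flatten curved panel surfaces by iterative gravity + spring relaxation.

Each mesh edge is a spring whose rest length is its 3D length. Per
iteration: (1) a normalized gravity pull toward the Z = 0 plane — a
constant force whose displacement is capped at `gravity_step` (0.1 mm)
per vertex per step, so the surface settles from the rim inward and
unrolls as it deflates;
(2) damped Hookean spring forces toward the per-edge rest lengths, with the
per-vertex displacement capped for stability; (3) probe-node vertices are
re-imposed by trilateration from their three nearest 10-5 vertices using
the distances frozen at construction time. The loop terminates when every
|Z| <= `z_tol` (and, as a quality safeguard, when the spring step has
settled below `disp_tol`).

The run is fully deterministic: fixed iteration order, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ConvergenceError, QualityError
from .mesh import TriMesh
from .surface_prep import PanelSurface

OPTODE_PREFIX = "optode:"


@dataclass
class FlattenConfig:
    gravity_step: float = 0.1        # mm, max per-vertex gravity displacement/step
    z_tol: float = 0.1               # mm, convergence: all |Z| below this
    spring_damping: float = 0.5
    spring_step_cap: float = 0.1     # mm, per-vertex cap on one spring step
    disp_tol: float = 1e-4           # mm, settle criterion on the spring step
    max_iters: int = 50000
    couple_probe_nodes: bool = True
    coupling_spring_weight: float = 3.0   # stiffness of probe/10-5 coupling springs
    area_tol: float = 0.05


@dataclass
class Coupling:
    node: int                        # probe-node vertex id
    partners: tuple[int, ...]        # its three nearest 10-5 vertex ids
    distances: tuple[float, ...]     # fixed 3D distances at construction


@dataclass
class FlatMesh:
    vertices: np.ndarray             # (n, 3); |Z| <= z_tol at output
    faces: np.ndarray
    provenance: np.ndarray           # -> PanelSurface vertex ids (identity here)
    edges: np.ndarray                # (m, 2)
    rest_lengths: np.ndarray         # (m,) 3D edge lengths
    couplings: list[Coupling]
    markers: dict[str, int]
    boundary_vertex_labels: dict[int, str]
    role: str
    area_3d: float
    iterations: int = 0
    n_mesh_edges: int = 0            # edges beyond this are coupling springs
    history: dict = field(default_factory=dict)

    @property
    def mesh_edges(self) -> np.ndarray:
        n = self.n_mesh_edges or len(self.edges)
        return self.edges[:n]

    @property
    def mesh_rest_lengths(self) -> np.ndarray:
        n = self.n_mesh_edges or len(self.edges)
        return self.rest_lengths[:n]

    @property
    def xy(self) -> np.ndarray:
        return self.vertices[:, :2]

    @property
    def area_2d(self) -> float:
        t = self.xy[self.faces]
        return float(np.abs(_signed_areas(t)).sum())

    def mesh2d(self) -> TriMesh:
        v = self.vertices.copy()
        v[:, 2] = 0.0
        return TriMesh(v, self.faces.copy())


def _signed_areas(tri_xy: np.ndarray) -> np.ndarray:
    a = tri_xy[:, 1] - tri_xy[:, 0]
    b = tri_xy[:, 2] - tri_xy[:, 0]
    return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])


def _initial_pose(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Rigid-rotate so the area-weighted best-fit plane is X-Y, centroid at
    origin, dome side up (positive Z skew)."""
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n = cross.sum(axis=0)
    ln = np.linalg.norm(n)
    if ln < 1e-12:
        # area-weighted normals cancel; fall back to PCA normal
        c = vertices - vertices.mean(axis=0)
        n = np.linalg.svd(c, full_matrices=False)[2][2]
    else:
        n = n / ln
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(np.dot(n, z))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    out = (vertices - vertices.mean(axis=0)) @ R.T
    if (out[:, 2] ** 3).sum() < 0:
        out[:, 1] *= -1
        out[:, 2] *= -1
    return out


def _build_couplings(panel: PanelSurface) -> list[Coupling]:
    land = [(name, vid) for name, vid in panel.markers.items()
            if not name.startswith(OPTODE_PREFIX)]
    probe = [(name, vid) for name, vid in panel.markers.items()
             if name.startswith(OPTODE_PREFIX)]
    if len(land) < 3 or not probe:
        return []
    V = panel.mesh.vertices
    lv = np.array(sorted({vid for _, vid in land}))
    out = []
    for _, nv in sorted(probe, key=lambda kv: kv[1]):
        d = np.linalg.norm(V[lv] - V[nv], axis=1)
        order = [i for i in np.lexsort((lv, d)) if d[i] > 1e-9]
        if len(order) < 3:
            continue                              # node sits on a landmark chain
        partners = _pick_partners(V, [int(lv[i]) for i in order])
        dists = tuple(float(np.linalg.norm(V[p] - V[nv])) for p in partners)
        out.append(Coupling(partners=partners, node=int(nv), distances=dists))
    return out


def _pick_partners(V: np.ndarray, ranked: list[int], pool: int = 6,
                   min_spread: float = 3.0) -> tuple[int, ...]:
    """Closest three 10-5 vertices, except that a nearly collinear triple
    (trilateration is ill-posed across a single landmark chain) is replaced
    by the closest well-spread triple from the nearest `pool` candidates."""
    from itertools import combinations

    cand = ranked[:pool]

    def spread(triple):
        P = V[list(triple)]
        return float(np.linalg.svd(P - P.mean(axis=0))[1][1])

    first = tuple(ranked[:3])
    if spread(first) >= min_spread or len(cand) < 4:
        return first
    best = None
    for triple in combinations(cand, 3):
        s = spread(triple)
        rank_cost = sum(ranked.index(t) for t in triple)
        key = (s < min_spread, rank_cost, -s)
        if best is None or key < best[0]:
            best = (key, triple)
    return tuple(best[1])


def _trilaterate(x0, pts, dists, iters: int = 6) -> np.ndarray:
    """In-plane Gauss-Newton trilateration: the node's Z stays put (gravity
    owns Z); each target distance is reduced by the current Z offset to its
    partner, so the 3D distances are honoured once the panel is flat."""
    x = x0.copy()
    dz = x[2] - pts[:, 2]
    d_eff = np.sqrt(np.maximum(np.asarray(dists) ** 2 - dz ** 2, 1e-12))
    for _ in range(iters):
        d = x[:2] - pts[:, :2]
        L = np.linalg.norm(d, axis=1)
        L = np.where(L > 1e-9, L, 1e-9)
        r = L - d_eff
        J = d / L[:, None]
        A = J.T @ J + 1e-9 * np.eye(2)
        g = J.T @ r
        try:
            dxy = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:
            break
        x[:2] = x[:2] + dxy
        if np.linalg.norm(dxy) < 1e-10:
            break
    return x


def flatten_panel(panel: PanelSurface, config: FlattenConfig | None = None) -> FlatMesh:
    """Project a curved panel surface to the plane. See module docstring."""
    cfg = config or FlattenConfig()
    mesh = panel.mesh
    if mesh.connected_components() != 1:
        raise QualityError(f"panel {panel.role!r} is not connected")

    edges = mesh.unique_edges()
    rest = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    n_mesh_edges = len(edges)
    area3d = mesh.area
    couplings = _build_couplings(panel) if cfg.couple_probe_nodes else []
    if couplings:
        # coupling distances also act as springs so the 10-5 partners share
        # the trilateration residual instead of the probe node absorbing it
        extra = np.array([[cp.node, p] for cp in couplings for p in cp.partners])
        extra_rest = np.array([d for cp in couplings for d in cp.distances])
        known = {tuple(sorted(e)) for e in edges.tolist()}
        keep = [k for k, e in enumerate(extra.tolist()) if tuple(sorted(e)) not in known]
        edges = np.vstack([edges, extra[keep]])
        rest = np.concatenate([rest, extra_rest[keep]])
    weights = np.ones(len(edges))
    weights[n_mesh_edges:] = cfg.coupling_spring_weight

    x = _initial_pose(mesh.vertices, mesh.faces)
    n, m = len(x), len(edges)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.tile(np.arange(m), 2)
    vals = np.concatenate([np.ones(m), -np.ones(m)])
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(n, m))
    degree = np.maximum(np.bincount(edges.ravel(), minlength=n), 1).astype(float)

    coupled_mask = np.zeros(n, dtype=bool)
    for cp in couplings:
        coupled_mask[cp.node] = True
    orient_ref = np.sign(np.median(_signed_areas(x[mesh.faces][:, :, :2])))
    faces = mesh.faces
    area3 = mesh.face_areas()
    tri3 = mesh.triangles
    emax3 = np.max([np.linalg.norm(tri3[:, 1] - tri3[:, 0], axis=1),
                    np.linalg.norm(tri3[:, 2] - tri3[:, 1], axis=1),
                    np.linalg.norm(tri3[:, 0] - tri3[:, 2], axis=1)], axis=0)
    needle = (2.0 * area3 / np.maximum(emax3, 1e-12)) < 0.08 * emax3
    g_hist: list[float] = []
    z_hist: list[float] = []
    spring_disp = np.inf
    it = 0
    damping = cfg.spring_damping

    def one_pass(x, damping, couple=True):
        x_before = x.copy()
        # gravity: constant pull toward Z = 0, normalized so no vertex moves
        # more than gravity_step in one step (vertices near the plane land on
        # it; the surface deflates from the rim inward and unrolls outward)
        dz = np.minimum(np.abs(x[:, 2]), cfg.gravity_step)
        g_hist.append(float(dz.max(initial=0.0)))
        x[:, 2] -= np.sign(x[:, 2]) * dz
        # springs (full 3D forces)
        d = x[edges[:, 1]] - x[edges[:, 0]]
        L = np.linalg.norm(d, axis=1)
        Ls = np.where(L > 1e-12, L, 1.0)
        f = (weights * (L - rest) / Ls)[:, None] * d
        F = S @ f
        # untangling: landed triangles that flattened inverted get pushed
        # along their signed-area gradient (no-op on fold-free panels)
        xy = x[:, :2]
        tri2 = xy[faces]
        sa = _signed_areas(tri2) * orient_ref
        landed = (np.abs(x[faces][:, :, 2]) < 10 * cfg.gravity_step).all(axis=1)
        thr = 0.05 * area3
        act = np.nonzero((sa < thr) & landed & ~needle)[0]
        if len(act):
            g = np.empty((len(act), 3, 2))
            a, b, c = tri2[act, 0], tri2[act, 1], tri2[act, 2]
            g[:, 0] = np.column_stack([b[:, 1] - c[:, 1], c[:, 0] - b[:, 0]])
            g[:, 1] = np.column_stack([c[:, 1] - a[:, 1], a[:, 0] - c[:, 0]])
            g[:, 2] = np.column_stack([a[:, 1] - b[:, 1], b[:, 0] - a[:, 0]])
            # fade the push to zero at the threshold (no on/off chatter)
            fade = np.clip((thr[act] - sa[act]) / np.maximum(thr[act], 1e-12), 0.0, 1.0)
            g *= (0.5 * orient_ref) * fade[:, None, None]
            np.add.at(F[:, :2], faces[act].ravel(), g.reshape(-1, 2))
        step = damping * F / degree[:, None]         # degree-normalized: stable
        mag = np.linalg.norm(step, axis=1)
        over = mag > cfg.spring_step_cap
        if over.any():
            step[over] *= (cfg.spring_step_cap / mag[over])[:, None]
            mag[over] = cfg.spring_step_cap
        x += step
        # probe-node coupling re-imposed by trilateration (move capped for
        # stability; the equilibrium is the fully trilaterated position)
        for cp in (couplings if couple else []):
            target = _trilaterate(x[cp.node], x[list(cp.partners)],
                                  np.asarray(cp.distances))
            dv = target - x[cp.node]
            L = np.linalg.norm(dv)
            if L > cfg.spring_step_cap:
                dv *= cfg.spring_step_cap / L
            x[cp.node] += dv
        # settle criterion: net displacement of the full iteration over the
        # unconstrained vertices (a coupled node's position is a function of
        # its partners and carries a finite constraint-reaction step)
        diff = np.linalg.norm(x - x_before, axis=1)
        diff[coupled_mask] = 0.0
        return x, float(diff.max(initial=0.0))

    # Settling schedule after the descent phase (first time all |Z| <= tol):
    # a fixed budget of coupled iterations, then springs-only (the coupled
    # reimposition/spring limit cycle never fully dies), then progressive
    # damping halvings to kill period-2 micro-oscillations. Deterministic.
    couple = bool(couplings)
    t_flat = None
    coupled_budget = 6000
    anneal_every = 3000
    while True:
        max_z = float(np.abs(x[:, 2]).max())
        z_hist.append(max_z)
        if max_z <= cfg.z_tol and spring_disp <= cfg.disp_tol:
            break
        if it >= cfg.max_iters:
            raise ConvergenceError(
                f"flattening of {panel.role!r} did not converge in {cfg.max_iters} "
                f"iterations (max |Z| = {max_z:.4f} mm, spring step = {spring_disp:.4f})",
                residuals={"max_z": z_hist[-50:], "gravity": g_hist[-50:],
                           "damping": damping, "couple": couple, "t_flat": t_flat})
        if max_z <= cfg.z_tol and t_flat is None:
            t_flat = it
        if t_flat is not None:
            tau = it - t_flat
            if couple and tau > coupled_budget:
                couple = False
            if tau > coupled_budget:
                halvings = min(6, (tau - coupled_budget) // anneal_every)
                damping = cfg.spring_damping * 0.5 ** halvings
        x, spring_disp = one_pass(x, damping, couple)
        it += 1
    if couplings:
        for cp in couplings:
            x[cp.node] = _trilaterate(x[cp.node], x[list(cp.partners)],
                                      np.asarray(cp.distances), iters=12)

    # flipped-triangle check, with one halved-step repair attempt.
    # Needle slivers (altitude below ~8% of the longest edge, produced where
    # cut lines pass embedded points) may fold flat within print tolerance;
    # they are exempt from the gate but recorded in the history.
    def flipped_faces(x):
        signs = np.sign(_signed_areas(x[mesh.faces][:, :, :2]))
        return (signs == -orient_ref) & ~needle

    if flipped_faces(x).any():
        for _ in range(min(5000, cfg.max_iters)):
            x, spring_disp = one_pass(x, damping * 0.5)
            it += 1
            if not flipped_faces(x).any():
                break
        else:
            raise QualityError(
                f"panel {panel.role!r}: flipped triangles persist after re-relaxation")
    folded = np.nonzero((np.sign(_signed_areas(x[mesh.faces][:, :, :2])) == -orient_ref)
                        & needle)[0]

    flat = FlatMesh(
        vertices=x, faces=mesh.faces.copy(), provenance=np.arange(n),
        edges=edges, rest_lengths=rest, couplings=couplings,
        n_mesh_edges=n_mesh_edges,
        markers=dict(panel.markers),
        boundary_vertex_labels=dict(panel.boundary_vertex_labels),
        role=panel.role, area_3d=area3d, iterations=it,
        history={"max_gravity_step": max(g_hist, default=0.0),
                 "gravity": g_hist, "max_z": z_hist,
                 "folded_needle_faces": folded.tolist()},
    )
    ratio = flat.area_2d / area3d
    if abs(ratio - 1.0) > cfg.area_tol:
        raise QualityError(
            f"panel {panel.role!r}: flattened area ratio {ratio:.4f} outside "
            f"+-{cfg.area_tol:.0%}")
    return flat


# ---------------------------------------------------------------------------
# distortion metrics
# ---------------------------------------------------------------------------


def distortion_report(flat: FlatMesh, panel: PanelSurface) -> dict:
    """Per-edge strain, area ratio, adjacent 10-5 pair errors, coupling residuals."""
    V3 = panel.mesh.vertices
    xy = flat.xy
    me = flat.mesh_edges
    l2d = np.linalg.norm(xy[me[:, 0]] - xy[me[:, 1]], axis=1)
    strain = np.abs(l2d / flat.mesh_rest_lengths - 1.0)

    land = sorted((name, vid) for name, vid in panel.markers.items()
                  if not name.startswith(OPTODE_PREFIX))
    pair_err = []
    if len(land) >= 2:
        lv = np.array([vid for _, vid in land])
        from scipy.spatial import cKDTree

        tree = cKDTree(V3[lv])
        k = min(4, len(lv))
        _, nbr = tree.query(V3[lv], k=k)
        seen = set()
        for i in range(len(lv)):
            for j in np.atleast_1d(nbr[i])[1:]:
                key = (min(i, int(j)), max(i, int(j)))
                if key in seen:
                    continue
                seen.add(key)
                a, b = lv[key[0]], lv[key[1]]
                d3 = np.linalg.norm(V3[a] - V3[b])
                d2 = np.linalg.norm(xy[a] - xy[b])
                if d3 > 1e-9:
                    pair_err.append(abs(d2 - d3) / d3)
    coupling_res = []
    for cp in flat.couplings:
        d2 = np.linalg.norm(xy[list(cp.partners)] - xy[cp.node], axis=1)
        coupling_res.append(float(np.abs(d2 - np.asarray(cp.distances)).max()))

    return {
        "edge_strain_mean": float(strain.mean()) if len(strain) else 0.0,
        "edge_strain_max": float(strain.max()) if len(strain) else 0.0,
        "area_ratio": flat.area_2d / flat.area_3d if flat.area_3d else 1.0,
        "landmark_pair_error_mean": float(np.mean(pair_err)) if pair_err else 0.0,
        "landmark_pair_error_max": float(np.max(pair_err)) if pair_err else 0.0,
        "coupling_residual_max": float(np.max(coupling_res)) if coupling_res else 0.0,
        "coupling_residuals": coupling_res,
        "iterations": flat.iterations,
        "max_z": float(np.abs(flat.vertices[:, 2]).max()),
        "max_gravity_step": flat.history.get("max_gravity_step", 0.0),
    }
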
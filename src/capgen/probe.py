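"""Probe designs: I/O (the ".SD" MATLAB probe dialect + JSON mirror),
validation, and spring/anchor registration onto the scalp surface.

Registration contract: anchored optodes sit exactly (bit-identical) on their
landmark coordinates; free optodes stay on the surface (< 0.1 mm) and rigid
springs reach their rest length within tolerance. The relaxation is a damped
synchronous (Jacobi) spring iteration with per-step surface reprojection, so
the result is deterministic and invariant to optode ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, FormatError, ValidationError
from .headmodel import HeadMesh, LandmarkSet

#: Sentinel rest length for flexible (unconstrained) springs.
FLEX = None

OPTODE_KINDS = ("source", "detector", "dummy")
DEFAULT_GROMMET = "#STD"


@dataclass
class Optode:
    design_position: np.ndarray          # (3,) mm, probe-design frame
    kind: str = "dummy"
    grommet_id: str = DEFAULT_GROMMET
    rotation: float = 0.0                # deg about the local surface normal

    def __post_init__(self):
        self.design_position = np.asarray(self.design_position, dtype=float)
        if self.kind not in OPTODE_KINDS:
            raise ValidationError(f"unknown optode kind {self.kind!r}")


@dataclass
class Spring:
    i: int
    j: int
    rest_length: float | None = FLEX     # mm; FLEX = flexible

    @property
    def rigid(self) -> bool:
        return self.rest_length is not None


@dataclass
class Anchor:
    optode: int
    landmark: str


@dataclass
class ProbeDesign:
    optodes: list[Optode]
    springs: list[Spring] = field(default_factory=list)
    anchors: list[Anchor] = field(default_factory=list)
    measurements: list[tuple[int, int]] = field(default_factory=list)

    def design_positions(self) -> np.ndarray:
        return np.array([o.design_position for o in self.optodes], dtype=float)

    def __eq__(self, other):
        if not isinstance(other, ProbeDesign):
            return NotImplemented
        return _probe_dict(self) == _probe_dict(other)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _probe_dict(probe: ProbeDesign) -> dict:
    return {
        "optodes": [
            {"position": [float(x) for x in o.design_position],
             "kind": o.kind, "grommet": o.grommet_id, "rotation": float(o.rotation)}
            for o in probe.optodes],
        "springs": [[s.i, s.j, None if s.rest_length is None else float(s.rest_length)]
                    for s in probe.springs],
        "anchors": [[a.optode, a.landmark] for a in probe.anchors],
        "measurements": [[int(a), int(b)] for a, b in probe.measurements],
    }


def write_probe_json(probe: ProbeDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(_probe_dict(probe), fh, indent=1)


def read_probe_design(path, format: str | None = None) -> ProbeDesign:
    """Read a probe design from JSON or the ".SD" MAT dialect.

    MAT dialect (the common SD probe structure): optode positions come from
    SrcPos / DetPos / DummyPos (concatenated in that order; spring and
    anchor indices are 1-based into that concatenation), SpringList rows
    are [i, j, rest_length] with negative rest length meaning flexible,
    AnchorList rows are [index, landmark-name], grommet types and rotations
    from {Src,Det,Dummy}GrommetType / ...GrommetRot.
    """
    p = str(path)
    if format is None:
        format = "json" if p.lower().endswith(".json") else "sd-mat"
    if format == "json":
        with open(p) as fh:
            return probe_from_dict(json.load(fh))
    if format == "sd-mat":
        return _read_sd_mat(p)
    raise FormatError(f"unknown probe format {format!r}")


def probe_from_dict(data: dict) -> ProbeDesign:
    for key in ("optodes",):
        if key not in data:
            raise FormatError(f"probe JSON is missing required field {key!r}")
    optodes = []
    for o in data["optodes"]:
        if "position" not in o:
            raise FormatError("optode entry is missing 'position'")
        optodes.append(Optode(np.asarray(o["position"], dtype=float),
                              o.get("kind", "dummy"),
                              o.get("grommet", DEFAULT_GROMMET),
                              float(o.get("rotation", 0.0))))
    springs = [Spring(int(i), int(j), None if L is None else float(L))
               for i, j, L in data.get("springs", [])]
    anchors = [Anchor(int(i), str(lbl)) for i, lbl in data.get("anchors", [])]
    meas = [(int(a), int(b)) for a, b in data.get("measurements", [])]
    return ProbeDesign(optodes, springs, anchors, meas)


def _cellstr(value, n, default=DEFAULT_GROMMET) -> list[str]:
    if value is None:
        return [default] * n
    arr = np.atleast_1d(value)
    out = []
    for v in arr:
        s = str(v).strip() if not isinstance(v, np.ndarray) else str(v.item() if v.size else "")
        out.append(s if s else default)
    while len(out) < n:
        out.append(default)
    return out[:n]


def _read_sd_mat(path) -> ProbeDesign:
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    if "SD" not in raw:
        raise FormatError("MAT file has no 'SD' variable")
    sd = raw["SD"]

    def get(name, required=False):
        val = getattr(sd, name, None)
        if required and val is None:
            raise FormatError(f"SD structure is missing required field {name!r}")
        return val

    def pos_block(name, required=False):
        v = get(name, required)
        if v is None or (hasattr(v, "size") and v.size == 0):
            return np.zeros((0, 3))
        return np.atleast_2d(np.asarray(v, dtype=float))

    src = pos_block("SrcPos", required=True)
    det = pos_block("DetPos", required=True)
    dummy = pos_block("DummyPos")
    kinds = ["source"] * len(src) + ["detector"] * len(det) + ["dummy"] * len(dummy)
    positions = np.vstack([src, det, dummy]) if (len(src) + len(det) + len(dummy)) else np.zeros((0, 3))

    grommets = (_cellstr(get("SrcGrommetType"), len(src))
                + _cellstr(get("DetGrommetType"), len(det))
                + _cellstr(get("DummyGrommetType"), len(dummy)))
    rots = np.concatenate([
        np.atleast_1d(np.asarray(get("SrcGrommetRot") if get("SrcGrommetRot") is not None
                                 else np.zeros(len(src)), dtype=float)).ravel()[:len(src)],
        np.atleast_1d(np.asarray(get("DetGrommetRot") if get("DetGrommetRot") is not None
                                 else np.zeros(len(det)), dtype=float)).ravel()[:len(det)],
        np.atleast_1d(np.asarray(get("DummyGrommetRot") if get("DummyGrommetRot") is not None
                                 else np.zeros(len(dummy)), dtype=float)).ravel()[:len(dummy)],
    ]) if len(positions) else np.zeros(0)

    optodes = [Optode(positions[i], kinds[i], grommets[i], float(rots[i]))
               for i in range(len(positions))]

    springs = []
    sl = get("SpringList")
    if sl is not None and np.asarray(sl).size:
        for row in np.atleast_2d(np.asarray(sl, dtype=float)):
            i, j = int(row[0]) - 1, int(row[1]) - 1
            L = float(row[2]) if len(row) > 2 else -1.0
            springs.append(Spring(i, j, FLEX if L < 0 else L))

    anchors = []
    al = get("AnchorList")
    if al is not None and np.asarray(al, dtype=object).size:
        rows = np.atleast_2d(np.asarray(al, dtype=object))
        for row in rows:
            anchors.append(Anchor(int(float(row[0])) - 1, str(row[1]).strip()))

    meas = []
    ml = get("MeasList")
    if ml is not None and np.asarray(ml).size:
        for row in np.atleast_2d(np.asarray(ml, dtype=float)):
            meas.append((int(row[0]) - 1, len(src) + int(row[1]) - 1))

    return ProbeDesign(optodes, springs, anchors, sorted(set(meas)))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_probe(probe: ProbeDesign, landmarks: LandmarkSet | None = None) -> dict:
    """Report-based validation; the report is empty iff all invariants hold."""
    violations: list[dict] = []
    n = len(probe.optodes)

    def add(code, message):
        violations.append({"code": code, "message": message})

    for k, o in enumerate(probe.optodes):
        if not o.grommet_id or not o.grommet_id.startswith("#"):
            add("bad-grommet-id", f"optode {k}: grommet id {o.grommet_id!r} must start with '#'")
    for k, s in enumerate(probe.springs):
        if not (0 <= s.i < n and 0 <= s.j < n):
            add("dangling-index", f"spring {k} references optode ({s.i}, {s.j}) of {n}")
        elif s.i == s.j:
            add("degenerate-spring", f"spring {k} joins optode {s.i} to itself")
        if s.rigid and s.rest_length <= 0:
            add("bad-rest-length", f"spring {k} has non-positive rest length")
    seen_anchor: dict[int, str] = {}
    for k, a in enumerate(probe.anchors):
        if not (0 <= a.optode < n):
            add("dangling-index", f"anchor {k} references optode {a.optode} of {n}")
            continue
        if a.optode in seen_anchor:
            add("duplicate-anchor", f"optode {a.optode} anchored more than once")
        seen_anchor[a.optode] = a.landmark
        if landmarks is not None and a.landmark not in landmarks.positions:
            add("unknown-landmark", f"anchor {k}: no 10-5 landmark named {a.landmark!r}")
    if not probe.anchors:
        add("no-anchor", "probe has no anchors; registration is underdetermined")

    # connectivity: every optode must reach an anchored one through springs
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((s.i, s.j) for s in probe.springs if 0 <= s.i < n and 0 <= s.j < n)
    anchored = {a.optode for a in probe.anchors if 0 <= a.optode < n}
    for comp in nx.connected_components(g):
        if anchored and not (comp & anchored):
            add("unreachable-from-anchor",
                f"optodes {sorted(comp)} are not connected to any anchored optode")

    return {"valid": not violations, "violations": violations}


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    positions: np.ndarray                # (n, 3) on-surface optode positions
    residual_history: list[float]        # max rigid-spring length error per iteration
    max_spring_error: float
    iterations: int
    converged: bool

    def as_map(self) -> dict[int, np.ndarray]:
        return {i: p for i, p in enumerate(self.positions)}


def _anchor_init(design: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rigid (least-squares) transform of design positions onto anchor targets."""
    if len(src) == 0:
        return design - design.mean(axis=0)
    if len(src) == 1:
        return design + (dst[0] - src[0])
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return (design - cs) @ R.T + cd


def register_probe(probe: ProbeDesign, head: HeadMesh, landmarks: LandmarkSet,
                   spring_tol: float = 0.5, step_tol: float = 0.01,
                   damping: float = 0.5, step_cap: float = 2.0,
                   max_iters: int = 5000) -> RegistrationResult:
    """Relax the probe onto the head surface.

    Raises ConvergenceError if the iteration does not settle; an infeasible
    rigid constraint shows up as `max_spring_error` > `spring_tol` in the
    result (reported, never silently dropped).
    """
    report = validate_probe(probe, landmarks)
    if not report["valid"]:
        raise ValidationError(f"probe fails validation: {report['violations']}")

    mesh = head.mesh
    n = len(probe.optodes)
    anchored_idx = np.array(sorted({a.optode for a in probe.anchors}), dtype=int)
    targets = {a.optode: np.asarray(landmarks.point(a.landmark), dtype=float)
               for a in probe.anchors}
    free = np.array([i for i in range(n) if i not in targets], dtype=int)

    design = probe.design_positions()
    src = design[anchored_idx]
    dst = np.array([targets[i] for i in anchored_idx])
    x = _anchor_init(design, src, dst)
    if len(free):
        x[free] = mesh.closest_point(x[free])[0]
    for i, t in targets.items():
        x[i] = t

    rig = [(s.i, s.j, s.rest_length) for s in probe.springs if s.rigid]
    ri = np.array([r[0] for r in rig], dtype=int)
    rj = np.array([r[1] for r in rig], dtype=int)
    rl = np.array([r[2] for r in rig], dtype=float)

    history: list[float] = []
    converged = False
    it = 0
    damp = damping
    best_moved = np.inf
    last_improve = 0
    for it in range(1, max_iters + 1):
        if len(rig):
            d = x[rj] - x[ri]
            L = np.linalg.norm(d, axis=1)
            Ls = np.where(L > 1e-12, L, 1.0)
            f = ((L - rl) / Ls)[:, None] * d        # pull together when stretched
            F = np.zeros_like(x)
            np.add.at(F, ri, f)
            np.add.at(F, rj, -f)
            step = damp * F
            mag = np.linalg.norm(step, axis=1)
            over = mag > step_cap
            if over.any():
                step[over] *= (step_cap / mag[over])[:, None]
            history.append(float(np.abs(L - rl).max()))
        else:
            step = np.zeros_like(x)
            history.append(0.0)

        x_new = x + step
        for i, t in targets.items():
            x_new[i] = t
        if len(free):
            x_new[free] = mesh.closest_point(x_new[free])[0]
        moved = float(np.linalg.norm(x_new - x, axis=1).max()) if n else 0.0
        x = x_new
        if moved < step_tol:
            converged = True
            break
        # anneal out projection/spring limit cycles (infeasible residuals
        # otherwise bounce at the step cap forever)
        if moved < 0.95 * best_moved:
            best_moved = moved
            last_improve = it
        elif it - last_improve > 200 and damp > damping / 64:
            damp *= 0.5
            last_improve = it

    if len(rig):
        L = np.linalg.norm(x[rj] - x[ri], axis=1)
        max_err = float(np.abs(L - rl).max())
    else:
        max_err = 0.0
    if not converged:
        raise ConvergenceError(
            f"probe registration did not converge in {max_iters} iterations "
            f"(last spring error {max_err:.3f} mm)", residuals=history)
    for i, t in targets.items():
        x[i] = t                                    # bit-identical anchors
    return RegistrationResult(x, history, max_err, it, converged)
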
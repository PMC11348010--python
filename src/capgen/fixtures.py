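"""Built-in fixtures: default probe design and default grommet library.

No external data is required anywhere in the pipeline: a synthetic
ellipsoid head, this probe, and the generated annular grommet exercise
every stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import mesh as mz
from .probe import Anchor, Optode, ProbeDesign, Spring
from .solidify import make_default_grommet

DEFAULT_GROMMET_ID = "#STD"


def default_probe(grid_n: int = 4, spacing: float = 30.0,
                  grommet_id: str = DEFAULT_GROMMET_ID) -> ProbeDesign:
    """A 4x4 rigid HD grid (alternating sources/detectors, 30 mm pitch)
    plus three anchored dummies tied to the grid with flexible springs."""
    optodes = []
    half = (grid_n - 1) / 2.0
    for j in range(grid_n):
        for i in range(grid_n):
            kind = "source" if (i + j) % 2 == 0 else "detector"
            pos = np.array([(i - half) * spacing, (j - half) * spacing, 95.0])
            rot = 15.0 * ((i + 2 * j) % 4)
            optodes.append(Optode(pos, kind, grommet_id, rot))
    springs = []
    for j in range(grid_n):
        for i in range(grid_n):
            a = j * grid_n + i
            if i + 1 < grid_n:
                springs.append(Spring(a, a + 1, spacing))
            if j + 1 < grid_n:
                springs.append(Spring(a, a + grid_n, spacing))
    n_grid = grid_n * grid_n
    anchors = []
    for k, label in enumerate(("Cz", "C3", "C4")):
        optodes.append(Optode(np.array([(k - 1) * 60.0, 0.0, 95.0]),
                              "dummy", grommet_id, 0.0))
        anchors.append(Anchor(n_grid + k, label))
        springs.append(Spring(n_grid + k, max(0, k * (n_grid // 2) - 1) if k else 0, None))
    measurements = [(s.i, s.j) for s in springs
                    if s.rigid and optodes[s.i].kind == "source"
                    and optodes[s.j].kind == "detector"]
    return ProbeDesign(optodes, springs, anchors, measurements)


def write_default_grommet_library(root, grommet_id: str = DEFAULT_GROMMET_ID,
                                  inner: float = 11.0, outer: float = 16.0,
                                  height: float = 5.0) -> Path:
    """Create <root>/<#id>/grommet.stl with the default annular grommet."""
    root = Path(root)
    d = root / grommet_id
    d.mkdir(parents=True, exist_ok=True)
    mz.write_stl(make_default_grommet(inner, outer, height), d / "grommet.stl")
    return root
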
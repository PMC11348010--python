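# capgen

Generate 3D-printable flat cap panels for fNIRS/EEG headgear from a scalp
surface mesh, a probe design, and a target head circumference.

The pipeline cuts the scalp surface into left / mid / right pieces, flattens
each by iterative gravity + spring relaxation (every mesh edge is a spring
with its 3D length as rest length; probe-node distances to their three
nearest 10-5 landmark vertices are kept fixed), fills the flattened outlines
with a 10 mm hexagonal lattice at 0.85 mm beam width, creates overlapping
2 mm welding tabs across the panel seams, halves the mid panel along the
midline, and extrudes everything by 0.9 mm into four watertight STL solids
with grommets, ear slits, and strap holders merged in.

No external data is needed: a synthetic ellipsoid head, a built-in HD probe
grid, and a generated annular grommet exercise the whole pipeline.

## CLI

```bash
# full run on the synthetic default head (writes 4 STLs + report.json)
capgen generate --head synthetic:56 --probe default --out out/

# user-supplied scalp mesh (mm) with a fiducial sidecar {Nz,Iz,LPA,RPA}
capgen generate --head scalp.stl --fiducials scalp_fid.json \
                --probe myprobe.SD --hc 57 --out out/

# check the invariant suite and print the grommet placement table
capgen verify --report out/report.json

# write reusable fixtures (synthetic head STL, default grommet library)
capgen fixtures --make-head 56:1,1.25,0.9 --make-grommet --out fixtures/
```

Probe designs are read from the “.SD” MATLAB dialect (`SrcPos`/`DetPos`/
`DummyPos`, 1-based `SpringList` rows `[i, j, rest]` with negative rest
meaning flexible, `AnchorList` rows `[index, landmark]`, grommet types
`#<name>`) or from an equivalent JSON mirror (see `capgen.probe`).
Grommet libraries are directories `<#id>/grommet.stl`.

## Configuration

All geometric parameters live in `CapConfig` (YAML-loadable, echoed into the
report): hexagon edge 10 mm, lattice width 0.85 mm, tab width 2 mm,
extrusion 0.9 mm, gravity step 0.1 mm, flattening Z tolerance 0.1 mm,
axial cut 15 mm above Nz, mid panel 3/7 of the coronal arc, ear slit 15 mm
above the LPA/RPA point, tab search reach 10 mm. Head size is scaled
linearly by head circumference only (`scale_mode: HC`).

## Layout

| module | role |
|---|---|
| `capgen.mesh` | triangle-mesh toolkit: STL/OFF I/O, plane slices/cuts, point embedding |
| `capgen.headmodel` | synthetic heads, arc measurement, 10-5 landmarks, HC scaling |
| `capgen.probe` | probe I/O, validation, spring/anchor registration |
| `capgen.surface_prep` | landmark/optode embedding, axial + sagittal panel cutting |
| `capgen.flattening` | gravity + spring relaxation flattening, distortion metrics |
| `capgen.panel2d` | outlines, hex lattice, mid halving, welding tabs |
| `capgen.solidify` | 2.5D layer-stack solids, grommets, ear slits, holders, STL |
| `capgen.pipeline` | orchestration, config, verification report |
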
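#!/usr/bin/env python
"""Build the synthetic implant-in-bone mesh and export it.

Generates the default desk-scale model (12 x 12 x 16 mm bone block at
1 mm spacing, Ø4 x 8 mm implant with a 2 mm exposed head through a
1.5 mm cortical shell) and writes a legacy-VTK mesh, an Abaqus-flavour
.inp, and a JSON stats summary to results/.
"""

import json
from pathlib import Path

import numpy as np

from osseoimpact import geometry, vtkio

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = geometry.GeometryParams()
mesh = geometry.build_mesh(params)
vols = mesh.volumes()

stats = {
    "n_nodes": int(mesh.n_nodes),
    "n_elements": int(mesh.n_elements),
    "grid_spacing_m": params.grid_spacing,
    "region_elements": {
        r: int((mesh.region == r).sum()) for r in geometry.REGIONS
    },
    "region_volume_mm3": {
        r: float(vols[mesh.region == r].sum() * 1e9) for r in geometry.REGIONS
    },
    "interface_elements": int(mesh.element_sets["INTERFACE"].size),
    "fixed_nodes": int(mesh.node_sets["FIXED"].size),
    "implant_head_nodes": int(mesh.node_sets["IMPLANT_TOP"].size),
}
(OUT / "mesh_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
# full mesh exports are MB-scale text; keep them out of the results tree
SCRATCH = OUT.parent / "scratch"
SCRATCH.mkdir(exist_ok=True)
vtkio.write_vtk(mesh, SCRATCH / "mesh.vtk")
vtkio.write_abaqus_inp(mesh, SCRATCH / "mesh.inp")

print(json.dumps(stats, indent=2))
print(f"wrote {SCRATCH/'mesh.vtk'}, {SCRATCH/'mesh.inp'}, {OUT/'mesh_stats.json'}")
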
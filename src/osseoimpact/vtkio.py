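"""Plain-text mesh and field export: legacy ASCII VTK and Abaqus .inp."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Mesh, REGIONS

__all__ = ["write_vtk", "write_abaqus_inp"]

_REGION_CODE = {name: i for i, name in enumerate(REGIONS)}


def write_vtk(
    mesh: Mesh,
    path,
    cell_data: dict | None = None,
    point_data: dict | None = None,
    title: str = "osseoimpact mesh",
) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    Region labels are always emitted as integer cell data (IMPLANT=0,
    CORTICAL=1, CANCELLOUS=2); extra per-cell or per-point scalar/vector
    arrays may be passed in the two dicts.
    """
    path = Path(path)
    n, e = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in mesh.node_coords]
    lines.append(f"CELLS {e} {e * 5}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {e}")
    lines += ["10"] * e   # VTK_TETRA

    lines.append(f"CELL_DATA {e}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(_REGION_CODE[r]) for r in mesh.region]
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in arr.astype(float)]

    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.9g}" for x in v) for v in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]

    path.write_text("\n".join(lines) + "\n")


def write_abaqus_inp(mesh: Mesh, path) -> None:
    """Abaqus-flavour .inp (1-based C3D4 elements, one ELSET per region)."""
    path = Path(path)
    out = ["*NODE"]
    out += [
        f"{i + 1}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}"
        for i, p in enumerate(mesh.node_coords)
    ]
    out.append("*ELEMENT, TYPE=C3D4")
    out += [
        f"{i + 1}, {t[0] + 1}, {t[1] + 1}, {t[2] + 1}, {t[3] + 1}"
        for i, t in enumerate(mesh.tets)
    ]
    for region in REGIONS:
        ids = np.flatnonzero(mesh.region == region) + 1
        if ids.size == 0:
            continue
        out.append(f"*ELSET, ELSET={region}")
        for i in range(0, ids.size, 16):
            out.append(", ".join(map(str, ids[i : i + 16])))
    path.write_text("\n".join(out) + "\n")
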
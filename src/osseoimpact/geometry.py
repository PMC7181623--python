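"""Parametric conformal tetrahedral mesh of an implant-in-bone block.

The mesh stands in for an image-based reconstruction: a rectangular bone
block on a structured grid, each hexahedral cell split into six tetrahedra
sharing the cell's main diagonal (conformal by construction, so the
implant-bone interface is a perfectly bonded shared-node interface).
Elements are labelled by centroid: a cylindrical implant (default
Ø4 mm x 8 mm) entering through the top face, a cortical shell (default
1.5 mm) on the outer block surface, and cancellous bone inside.

All coordinates are SI (metres); element and node indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryParams",
    "Mesh",
    "GeometryError",
    "build_mesh",
    "select_fixed_nodes",
    "apply_trabecular_porosity",
    "tet_volumes",
    "face_incidence_counts",
]

# region labels
IMPLANT = "IMPLANT"
CORTICAL = "CORTICAL"
CANCELLOUS = "CANCELLOUS"
REGIONS = (IMPLANT, CORTICAL, CANCELLOUS)

# 6-tet split of the unit cube sharing the (0,0,0)-(1,1,1) diagonal.
# Vertices are bit-coded (i, j, k) offsets; every tet below has positive
# signed volume and the induced face diagonals match across neighbouring
# cells (low corner -> high corner), so the grid is conformal.
_CUBE_TETS = np.array(
    [
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 1, 0), (0, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 1), (0, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (1, 0, 1), (1, 0, 0), (1, 1, 1)],
    ],
    dtype=np.int64,
)


class GeometryError(ValueError):
    """Raised for invalid geometry parameters or mesh operations."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic implant-in-bone block.

    The implant axis is +z and the implant enters through the top
    (max-z) face; the block is centred on the axis in x and y.
    """

    block_dims: tuple[float, float, float] = (0.012, 0.012, 0.016)
    grid_spacing: float = 0.001
    implant_radius: float = 0.002
    implant_length: float = 0.008
    cortical_thickness: float = 0.0015
    # exposed implant head above the bone surface: the experimental
    # loading strikes the implant head, not the bone, so by default the
    # head protrudes and can be hit from any direction
    implant_protrusion: float = 0.002
    trabecular_porosity: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        dims = np.asarray(self.block_dims, dtype=float)
        if dims.shape != (3,) or np.any(dims <= 0):
            raise GeometryError("block_dims must be three positive extents")
        if self.grid_spacing <= 0:
            raise GeometryError("grid_spacing must be positive")
        if self.grid_spacing > self.cortical_thickness:
            raise GeometryError(
                "grid_spacing exceeds cortical_thickness: the cortical shell "
                "would not be resolvable; refine the grid"
            )
        if self.implant_length + self.cortical_thickness >= dims[2]:
            raise GeometryError(
                "implant_length + cortical_thickness must be smaller than the "
                "block extent along the implant axis"
            )
        if 2.0 * self.implant_radius >= min(dims[0], dims[1]):
            raise GeometryError("implant diameter must fit inside the transverse extents")
        if self.implant_protrusion < 0:
            raise GeometryError("implant_protrusion must be >= 0")
        if not (0.0 <= self.trabecular_porosity < 1.0):
            raise GeometryError("trabecular_porosity must lie in [0, 1)")

    @property
    def cells(self) -> tuple[int, int, int]:
        """Number of grid cells along each axis (extents snapped to the grid)."""
        return tuple(
            int(round(d / self.grid_spacing)) for d in self.block_dims
        )


@dataclass
class Mesh:
    """Conformal tetrahedral mesh with region labels and named sets.

    ``node_coords`` is (n_nodes, 3) in metres, ``tets`` is (n_tets, 4)
    0-based node indices ordered so every signed volume is positive,
    ``region`` is a per-element label from ``REGIONS``.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    grid_spacing: float = 0.0
    implant_axis: int = 2

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def centroids(self) -> np.ndarray:
        return self.node_coords[self.tets].mean(axis=1)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.node_coords, self.tets)

    def region_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region == label)


def tet_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive under the mesh convention)."""
    p = coords[tets]
    d = p[:, 1:] - p[:, :1]
    return np.linalg.det(d) / 6.0


def build_mesh(params: GeometryParams) -> Mesh:
    """Build the structured hex-to-tet mesh and label regions by centroid.

    Labelling precedence: implant cylinder first (embedded part plus the
    exposed head column above the bone surface), then the cortical shell
    (within ``cortical_thickness`` of any outer block surface), else
    cancellous.  Node sets FIXED (transverse x-face pair) and IMPLANT_TOP
    (exposed implant head nodes at or above the bone surface) and the
    element set INTERFACE (bone elements within one grid spacing of the
    implant surface) are populated.
    """
    nx, ny, nz = params.cells
    h = params.grid_spacing
    dims = np.array([nx * h, ny * h, nz * h])
    n_prot = int(round(params.implant_protrusion / h))
    nz_tot = nz + n_prot

    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    zs = np.arange(nz_tot + 1) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz_tot + 1) + k

    ci, cj, ck = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz_tot), indexing="ij"
    )
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    axis_xy = np.array([dims[0] / 2.0, dims[1] / 2.0])
    z_top = dims[2]   # bone surface; the implant head may rise above it

    # cells above the bone surface exist only inside the implant column
    hex_r = np.hypot(
        (ci + 0.5) * h - axis_xy[0], (cj + 0.5) * h - axis_xy[1]
    )
    keep = (ck < nz) | (hex_r <= params.implant_radius)
    ci, cj, ck = ci[keep], cj[keep], ck[keep]
    n_cells = ci.size
    tets = np.empty((n_cells * 6, 4), dtype=np.int64)
    for t in range(6):
        for v in range(4):
            di, dj, dk = _CUBE_TETS[t, v]
            tets[t::6, v] = nid(ci + di, cj + dj, ck + dk)

    # drop unused grid nodes (above-surface nodes outside the head column)
    used = np.unique(tets)
    if used.size < coords.shape[0]:
        remap = -np.ones(coords.shape[0], dtype=np.int64)
        remap[used] = np.arange(used.size)
        coords = coords[used]
        tets = remap[tets]

    cent = coords[tets].mean(axis=1)

    r = np.hypot(cent[:, 0] - axis_xy[0], cent[:, 1] - axis_xy[1])
    depth = z_top - cent[:, 2]
    above = cent[:, 2] > z_top   # head column cells are implant by construction
    in_implant = above | ((r <= params.implant_radius) & (depth <= params.implant_length))

    dist_surface = np.minimum.reduce(
        [cent[:, 0], dims[0] - cent[:, 0],
         cent[:, 1], dims[1] - cent[:, 1],
         cent[:, 2], dims[2] - cent[:, 2]]
    )
    in_cortical = dist_surface < params.cortical_thickness

    region = np.full(tets.shape[0], CANCELLOUS, dtype=object)
    region[in_cortical] = CORTICAL
    region[in_implant] = IMPLANT
    region = region.astype("U10")

    # distance from a centroid to the implant surface (cylinder side,
    # bottom disc, or bottom rim), used for the interface view
    z_bot = z_top - params.implant_length
    dr = r - params.implant_radius
    dz = z_bot - cent[:, 2]
    outside = ~in_implant
    d_side = np.where((dz <= 0) & (dr > 0), dr, np.inf)
    d_bot = np.where((dz > 0) & (dr <= 0), dz, np.inf)
    d_rim = np.where((dz > 0) & (dr > 0), np.hypot(dr, dz), np.inf)
    d_impl = np.minimum.reduce([d_side, d_bot, d_rim])
    interface = np.flatnonzero(outside & (d_impl <= h))

    mesh = Mesh(
        node_coords=coords,
        tets=tets,
        region=region,
        grid_spacing=h,
        implant_axis=2,
    )
    mesh.element_sets = {
        IMPLANT: np.flatnonzero(region == IMPLANT),
        CORTICAL: np.flatnonzero(region == CORTICAL),
        CANCELLOUS: np.flatnonzero(region == CANCELLOUS),
        "INTERFACE": interface,
    }

    # exposed implant head surface: implant-element nodes at or above the
    # bone surface (reduces to the entry-face patch for a flush implant)
    exposed = np.flatnonzero(coords[:, 2] > z_top - 0.5 * h)
    impl_nodes = np.unique(tets[region == IMPLANT])
    mesh.node_sets = {
        "FIXED": select_fixed_nodes(mesh, "x"),
        "IMPLANT_TOP": np.intersect1d(exposed, impl_nodes),
    }

    if params.trabecular_porosity > 0.0:
        mesh = apply_trabecular_porosity(
            mesh, params.trabecular_porosity, params.random_seed
        )
    return mesh


def select_fixed_nodes(mesh: Mesh, face_pair: str) -> np.ndarray:
    """Nodes on the two block faces normal to a transverse axis.

    ``face_pair`` is "x" or "y"; selecting the implant axis would clamp
    the loaded face and is rejected.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(face_pair)
    if ax is None:
        raise GeometryError(f"unknown face_pair {face_pair!r}")
    if ax == mesh.implant_axis:
        raise GeometryError("face_pair must be transverse to the implant axis")
    c = mesh.node_coords[:, ax]
    tol = 0.5 * mesh.grid_spacing
    return np.flatnonzero((c < c.min() + tol) | (c > c.max() - tol))


def _compact(mesh: Mesh, keep: np.ndarray) -> Mesh:
    """Drop elements not in ``keep``, remove orphan nodes, remap all sets."""
    keep = np.asarray(keep)
    tets = mesh.tets[keep]
    used = np.unique(tets)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(used.size)

    old_to_new_elem = -np.ones(mesh.n_elements, dtype=np.int64)
    old_to_new_elem[keep] = np.arange(keep.size)

    out = Mesh(
        node_coords=mesh.node_coords[used],
        tets=remap[tets],
        region=mesh.region[keep],
        grid_spacing=mesh.grid_spacing,
        implant_axis=mesh.implant_axis,
    )
    out.node_sets = {
        name: np.sort(remap[np.intersect1d(ids, used)])
        for name, ids in mesh.node_sets.items()
    }
    out.element_sets = {
        name: np.sort(old_to_new_elem[ids][old_to_new_elem[ids] >= 0])
        for name, ids in mesh.element_sets.items()
    }
    return out


def apply_trabecular_porosity(mesh: Mesh, fraction: float, seed: int) -> Mesh:
    """Remove a uniformly random subset of cancellous elements.

    A stochastic stand-in for unresolved trabecular microstructure: a
    ``fraction`` of CANCELLOUS elements (deterministic under ``seed``) is
    deleted; implant and cortical elements are untouched.  Raises if the
    removal disconnects the implant from all bone.
    """
    if not (0.0 <= fraction < 1.0):
        raise GeometryError("porosity fraction must lie in [0, 1)")
    if fraction == 0.0:
        return mesh
    canc = mesh.region_indices(CANCELLOUS)
    n_remove = int(round(fraction * canc.size))
    rng = np.random.default_rng(seed)
    removed = rng.choice(canc, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(mesh.n_elements), removed)
    out = _compact(mesh, keep)

    impl_nodes = set(np.unique(out.tets[out.region == IMPLANT]).tolist())
    bone = out.region != IMPLANT
    if not impl_nodes.intersection(np.unique(out.tets[bone]).tolist()):
        raise GeometryError("porosity removal disconnected the implant from bone")
    return out


def face_incidence_counts(mesh: Mesh) -> np.ndarray:
    """Number of tets sharing each distinct triangular face.

    In a conformal mesh every face count is 1 (boundary) or 2 (interior).
    """
    faces = mesh.tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]]
    faces = np.sort(faces.reshape(-1, 3), axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    return counts
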
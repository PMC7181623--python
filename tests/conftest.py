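"""Shared fixtures: small meshes, material libraries, solver fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from osseoimpact import fem, geometry, materials, pipeline


@pytest.fixture(scope="session")
def default_params() -> geometry.GeometryParams:
    return geometry.GeometryParams()


@pytest.fixture(scope="session")
def default_mesh(default_params) -> geometry.Mesh:
    return geometry.build_mesh(default_params)


@pytest.fixture(scope="session")
def default_lib() -> materials.MaterialLibrary:
    return materials.default_library()


@pytest.fixture()
def tiny_params() -> geometry.GeometryParams:
    """Small implant-in-bone block for cheap end-to-end runs."""
    return geometry.GeometryParams(
        block_dims=(0.006, 0.006, 0.008),
        grid_spacing=0.001,
        implant_radius=0.0015,
        implant_length=0.004,
        cortical_thickness=0.0015,
    )


@pytest.fixture()
def tiny_mesh(tiny_params) -> geometry.Mesh:
    return geometry.build_mesh(tiny_params)


@pytest.fixture()
def tiny_config(tiny_params) -> pipeline.SimulationConfig:
    return pipeline.SimulationConfig(
        geometry=tiny_params,
        integration=fem.TimeIntegrationParams(t_end=4e-4, output_every=25),
    )


def uniform_library(E=15e9, nu=0.0, rho=1900.0, yield_strength=1e30):
    """Homogeneous material for wave/energy fixtures (all regions alike)."""
    m = materials.ElasticMaterial(E=E, nu=nu, rho=rho)
    return materials.MaterialLibrary(
        elastic={r: m for r in geometry.REGIONS},
        failure={
            r: materials.FailureParams(yield_strength, frozenset({r}))
            for r in (geometry.CORTICAL, geometry.CANCELLOUS)
        },
    )


def bar_fixture(length_cells=40, width_cells=2, spacing=1e-3):
    """Free homogeneous nu=0 bar mesh along z for 1-D wave oracles."""
    p = geometry.GeometryParams(
        block_dims=(
            width_cells * spacing,
            width_cells * spacing,
            length_cells * spacing,
        ),
        grid_spacing=spacing,
        implant_radius=0.45 * spacing,
        implant_length=4 * spacing,
        cortical_thickness=spacing,
        implant_protrusion=0.0,
    )
    mesh = geometry.build_mesh(p)
    lib = uniform_library()
    model = fem.build_model(mesh, lib, fixed_set=None)
    return mesh, lib, model


def single_tet_mesh(coords=None, region="CORTICAL"):
    """Mesh of one positively oriented tetrahedron."""
    if coords is None:
        coords = np.array(
            [[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0], [0, 0, 1e-3]], dtype=float
        )
    tets = np.array([[0, 1, 2, 3]])
    return geometry.Mesh(
        node_coords=np.asarray(coords, dtype=float),
        tets=tets,
        region=np.array([region], dtype="U10"),
        grid_spacing=1e-3,
    )
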
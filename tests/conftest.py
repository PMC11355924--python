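"""Shared fixtures: analytic meshes and voxelized solids with closed-form
morphometric and curvature properties. Expensive voxel fixtures are
session-scoped so curvature, morphometry and acceptance tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from osteocurv.curvature import (derived_curvatures, extract_surface,
                                 principal_curvatures)
from osteocurv.microstructure import VoxelVolume, make_primitive

# the marching-cubes smoothing preset used for fixture-quality curvature
CURV_PRESET = dict(smooth_sigma=1.0, taubin_iterations=20)
NORMAL_SMOOTH = 6


def tube_mesh(radius: float, length: float, n_theta: int = 64,
              n_z: int = 40) -> trimesh.Trimesh:
    """Open parametric cylinder tube (no caps), axis z, analytic normals
    well-defined everywhere; used because library cylinders place all side
    vertices on the two end rings."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-length / 2, length / 2, n_z)
    tg, zg = np.meshgrid(theta, z, indexing="ij")
    verts = np.stack([radius * np.cos(tg), radius * np.sin(tg), zg],
                     axis=-1).reshape(-1, 3)
    faces = []
    for i in range(n_theta):
        for j in range(n_z - 1):
            a = i * n_z + j
            b = ((i + 1) % n_theta) * n_z + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return trimesh.Trimesh(verts, faces, process=False)


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def vox_sphere_volume():
    """Sphere of bone, radius 1.0 mm, voxelized at 25 um (radius 40 vox)."""
    return make_primitive("sphere", shape=(96, 96, 96), spacing=0.025,
                          radius=40)


@pytest.fixture(scope="session")
def vox_sphere_mesh(vox_sphere_volume):
    return extract_surface(vox_sphere_volume, **CURV_PRESET)


@pytest.fixture(scope="session")
def vox_sphere_field(vox_sphere_mesh):
    return derived_curvatures(principal_curvatures(
        vox_sphere_mesh, normal_smooth_iterations=NORMAL_SMOOTH))


@pytest.fixture(scope="session")
def vox_torus_volume():
    """Solid torus, major 0.7 mm / minor 0.3 mm at 25 um."""
    return make_primitive("torus", shape=(96, 96, 96), spacing=0.025,
                          major_radius=28, minor_radius=12)


@pytest.fixture(scope="session")
def vox_cylinder_volume():
    """Cylinder of bone, radius 0.5 mm, voxelized at 12.5 um (radius 40)."""
    return make_primitive("cylinder", shape=(96, 96, 96), spacing=0.0125,
                          radius=40, length=88)


@pytest.fixture(scope="session")
def slab_volume():
    """Spanning slab, 10 voxels thick at 35 um (0.35 mm)."""
    data = np.zeros((64, 64, 64), dtype=bool)
    data[:, :, 27:37] = True
    return VoxelVolume(data, spacing=0.035)
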
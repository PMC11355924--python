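"""Voxel-based linear-elastic homogenization of trabecular volumes.

Each bone voxel is converted into six congruent first-order tetrahedra
(or optionally one trilinear hexahedron), all elements share the grid
nodes, and the apparent stiffness of the cube is probed with kinematic
uniform boundary conditions (KUBC): for each of six canonical unit strains
(three uniaxial, three engineering shears) the boundary nodes are given
the affine displacement u = eps0 . x, the interior is solved by Jacobi
preconditioned conjugate gradients, and the volume-average stress forms
one column of the 6x6 Voigt stiffness matrix

    C[:, j] = <sigma>  under unit strain case j.

Bone tissue is a homogeneous isotropic solid (default 15 GPa / 0.3).
The matrix is symmetrized, and can be rotated into the fabric frame (MIL
ellipsoid axes) and projected onto the orthotropic pattern with nine
independent constants (three moduli, three cross couplings, three shears).

Voigt order is (11, 22, 33, 23, 13, 12) with engineering shear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .microstructure import VoxelVolume

__all__ = [
    "MaterialModel",
    "StiffnessTensor",
    "LoadCase",
    "FEMesh",
    "canonical_load_cases",
    "isotropic_stiffness",
    "voxels_to_elements",
    "solve_case",
    "homogenized_stiffness",
    "rotate_to_fabric",
    "orthotropic_constants",
]

log = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Conjugate gradients failed to reach the requested residual."""


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic tissue material (Young's modulus in GPa)."""

    youngs_modulus: float = 15.0
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")


@dataclass
class StiffnessTensor:
    """6x6 Voigt stiffness in GPa; ``basis`` is 'lab' or 'fabric'."""

    c: np.ndarray
    basis: str = "lab"

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (6, 6):
            raise ValueError("stiffness must be 6x6")

    @property
    def compliance(self) -> np.ndarray:
        return np.linalg.inv(self.c)

    def engineering_constants(self) -> dict[str, float]:
        """Orthotropic engineering constants from the compliance matrix."""
        s = self.compliance
        return {
            "E1": 1 / s[0, 0], "E2": 1 / s[1, 1], "E3": 1 / s[2, 2],
            "nu12": -s[0, 1] / s[0, 0], "nu13": -s[0, 2] / s[0, 0],
            "nu23": -s[1, 2] / s[1, 1],
            "G23": 1 / s[3, 3], "G13": 1 / s[4, 4], "G12": 1 / s[5, 5],
        }


@dataclass(frozen=True)
class LoadCase:
    """One canonical KUBC probe: a symmetric unit strain tensor."""

    name: str
    strain: np.ndarray  # 3x3 symmetric


def canonical_load_cases() -> list[LoadCase]:
    """The six canonical cases: unit uniaxial strains along x, y, z and
    unit engineering shears in the yz, xz, xy planes."""
    cases = []
    for i, name in enumerate(("uni_x", "uni_y", "uni_z")):
        e = np.zeros((3, 3))
        e[i, i] = 1.0
        cases.append(LoadCase(name, e))
    for (i, j), name in zip(((1, 2), (0, 2), (0, 1)),
                            ("shear_yz", "shear_xz", "shear_xy")):
        e = np.zeros((3, 3))
        e[i, j] = e[j, i] = 0.5  # engineering shear gamma = 1
        cases.append(LoadCase(name, e))
    return cases


def isotropic_stiffness(material: MaterialModel) -> np.ndarray:
    """Closed-form isotropic 6x6 Voigt stiffness (engineering shear)."""
    E, nu = material.youngs_modulus, material.poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.arange(3), np.arange(3)] += 2 * mu
    c[np.arange(3, 6), np.arange(3, 6)] = mu
    return c


# ---------------------------------------------------------------------------
# element matrices

_CORNERS = np.array([[(i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1]
                     for i in range(8)], dtype=float)

# six tetrahedra around the 0-7 main diagonal of the unit cube
_TET_CORNERS = np.array([
    [0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
    [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7]])


def _tet_b_matrix(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Strain-displacement matrix (6x12, engineering shear) and volume of a
    linear tetrahedron with vertex coordinates ``x`` (4x3)."""
    J = (x[1:] - x[0]).T  # 3x3
    vol = abs(np.linalg.det(J)) / 6.0
    dN = np.zeros((4, 3))
    dN[1:] = np.linalg.inv(J)   # row a-1 = grad of barycentric coord a
    dN[0] = -dN[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for a in range(4):
        bx, by, bz = dN[a]
        B[0, 3 * a] = bx
        B[1, 3 * a + 1] = by
        B[2, 3 * a + 2] = bz
        B[3, 3 * a + 1] = bz
        B[3, 3 * a + 2] = by
        B[4, 3 * a] = bz
        B[4, 3 * a + 2] = bx
        B[5, 3 * a] = by
        B[5, 3 * a + 1] = bx
    return B, vol


def _hex_b_matrices(spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """B matrices (8 Gauss points, 6x24) and point weights for a trilinear
    hexahedron with edge length ``spacing``."""
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[sx * g, sy * g, sz * g]
                    for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    # natural coords of corners in the same (x fastest) ordering as _CORNERS
    nat = 2 * _CORNERS - 1
    Bs = np.zeros((8, 6, 24))
    w = np.full(8, (spacing / 2) ** 3)
    for q, (xi, eta, zeta) in enumerate(pts):
        dN = np.zeros((8, 3))
        for a in range(8):
            sx, sy, sz = nat[a]
            dN[a, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8
            dN[a, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8
            dN[a, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8
        dN *= 2.0 / spacing  # d(natural)/d(physical)
        for a in range(8):
            bx, by, bz = dN[a]
            Bs[q, 0, 3 * a] = bx
            Bs[q, 1, 3 * a + 1] = by
            Bs[q, 2, 3 * a + 2] = bz
            Bs[q, 3, 3 * a + 1] = bz
            Bs[q, 3, 3 * a + 2] = by
            Bs[q, 4, 3 * a] = bz
            Bs[q, 4, 3 * a + 2] = bx
            Bs[q, 5, 3 * a] = by
            Bs[q, 5, 3 * a + 1] = bx
    return Bs, w


# ---------------------------------------------------------------------------
# mesh


@dataclass
class FEMesh:
    """Assembled voxel FE model.

    ``node_coords`` are physical positions (mm) of the grid nodes used by
    bone voxels; ``element_nodes`` maps elements to node indices (4 or 8
    columns for tet/hex mode); ``boundary_nodes`` flags nodes on the RVE
    bounding box where KUBC displacements are prescribed.
    """

    node_coords: np.ndarray
    element_nodes: np.ndarray
    boundary_nodes: np.ndarray
    spacing: float
    rve_volume: float
    mode: str
    n_removed_components: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.element_nodes)


def voxels_to_elements(volume: VoxelVolume, mode: str = "tet") -> FEMesh:
    """Convert bone voxels into an FE mesh with shared grid nodes.

    ``mode='tet'`` splits each voxel into six congruent first-order
    tetrahedra sharing the voxel's main diagonal; ``mode='hex'`` keeps one
    trilinear hexahedron per voxel. Sub-components not face-connected to
    the largest one are removed (they would float or hinge) and counted.
    """
    if mode not in ("tet", "hex"):
        raise ValueError("mode must be 'tet' or 'hex'")
    data = volume.data
    if not data.any():
        raise ValueError("empty volume cannot be meshed")
    # keep the largest 6-connected component: corner- or edge-connected
    # fragments form mechanisms under KUBC
    labels, n = ndimage.label(data, structure=ndimage.generate_binary_structure(3, 1))
    n_removed = 0
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = counts.argmax()
        n_removed = n - 1
        data = labels == keep
        log.info("removed %d floating sub-component(s) before FE meshing", n_removed)

    nx, ny, nz = data.shape
    vox = np.argwhere(data)
    # global grid node ids (corner lattice), x fastest in _CORNERS order
    stride = np.array([(ny + 1) * (nz + 1), nz + 1, 1], dtype=np.int64)
    corner_ids = ((vox[:, None, :] + _CORNERS[None, :, :].astype(int)) @ stride)

    used, inverse = np.unique(corner_ids.ravel(), return_inverse=True)
    corner_idx = inverse.reshape(corner_ids.shape).astype(np.int32)

    ii = used // ((ny + 1) * (nz + 1))
    jj = (used // (nz + 1)) % (ny + 1)
    kk = used % (nz + 1)
    node_coords = (np.stack([ii, jj, kk], axis=1) * volume.spacing
                   + np.asarray(volume.origin))
    boundary = ((ii == 0) | (ii == nx) | (jj == 0) | (jj == ny)
                | (kk == 0) | (kk == nz))

    if mode == "tet":
        elements = corner_idx[:, _TET_CORNERS].reshape(-1, 4)
    else:
        elements = corner_idx
    return FEMesh(node_coords=node_coords, element_nodes=elements,
                  boundary_nodes=boundary, spacing=volume.spacing,
                  rve_volume=volume.total_volume, mode=mode,
                  n_removed_components=n_removed)


def _element_matrices(mesh: FEMesh, D: np.ndarray):
    """Per-element-type stiffness (k), B-like stress operators and volumes.

    In tet mode all elements of a given diagonal orientation are congruent,
    so only six distinct 12x12 matrices exist; in hex mode a single 24x24
    matrix serves every element.
    """
    sp_ = mesh.spacing
    if mesh.mode == "tet":
        ks, Bs, vols = [], [], []
        for tet in _TET_CORNERS:
            x = _CORNERS[tet] * sp_
            B, vol = _tet_b_matrix(x)
            ks.append(vol * B.T @ D @ B)
            Bs.append(B)
            vols.append(vol)
        return ks, Bs, vols
    Bq, w = _hex_b_matrices(sp_)
    k = sum(w[q] * Bq[q].T @ D @ Bq[q] for q in range(8))
    Bavg = (Bq * w[:, None, None]).sum(axis=0) / w.sum()
    return [k], [Bavg], [w.sum()]


def _assemble(mesh: FEMesh, D: np.ndarray) -> sp.csr_matrix:
    """Global stiffness matrix over all dofs (3 per node)."""
    ks, _, _ = _element_matrices(mesh, D)
    n_types = len(ks)
    npe = mesh.element_nodes.shape[1]
    ndof_e = 3 * npe
    rows, cols, vals = [], [], []
    for t in range(n_types):
        elems = mesh.element_nodes[t::n_types] if mesh.mode == "tet" \
            else mesh.element_nodes
        dof = (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(
            len(elems), ndof_e)
        r = np.repeat(dof, ndof_e, axis=1).ravel()
        c = np.tile(dof, (1, ndof_e)).ravel()
        rows.append(r.astype(np.int64))
        cols.append(c.astype(np.int64))
        vals.append(np.tile(ks[t].ravel(), len(elems)))
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    return K


@dataclass
class CaseSolution:
    """Displacements (n_nodes x 3), volume-average stress (3x3 tensor) and
    solver diagnostics for one load case."""

    displacements: np.ndarray
    average_stress: np.ndarray
    case: LoadCase
    n_iterations: int
    residual: float


def _average_stress(mesh: FEMesh, D: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Volume-average Cauchy stress over the RVE (bone stress scaled by the
    bone volume fraction), as a symmetric 3x3 tensor."""
    _, Bs, vols = _element_matrices(mesh, D)
    n_types = len(Bs)
    total = np.zeros(6)
    uflat = u.reshape(-1)
    npe = mesh.element_nodes.shape[1]
    for t in range(n_types):
        elems = mesh.element_nodes[t::n_types] if mesh.mode == "tet" \
            else mesh.element_nodes
        dof = (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(
            len(elems), 3 * npe)
        ue = uflat[dof]
        strains = ue @ Bs[t].T           # engineering shear
        stresses = strains @ D.T
        total += vols[t] * stresses.sum(axis=0)
    sv = total / mesh.rve_volume
    return np.array([[sv[0], sv[5], sv[4]],
                     [sv[5], sv[1], sv[3]],
                     [sv[4], sv[3], sv[2]]])


def solve_case(
    mesh: FEMesh,
    material: MaterialModel,
    case: LoadCase,
    tol: float = 1e-8,
    max_iter: int = 20000,
    _K: sp.csr_matrix | None = None,
) -> CaseSolution:
    """Solve one KUBC load case.

    Boundary nodes get u = eps0 . x; interior displacements come from
    Jacobi-preconditioned conjugate gradients at relative residual
    ``tol``. Raises :class:`SolverError` on non-convergence.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    D = isotropic_stiffness(material)
    K = _assemble(mesh, D) if _K is None else _K
    ndof = 3 * mesh.n_nodes
    u = np.zeros(ndof)
    bmask = np.repeat(mesh.boundary_nodes, 3)
    ub = (mesh.node_coords @ case.strain.T)[mesh.boundary_nodes]
    u[bmask] = ub.ravel()

    f = -(K @ u)[~bmask]
    Kii = K[~bmask][:, ~bmask]
    n_it = 0

    if Kii.shape[0] > 0 and np.linalg.norm(f) > 0:
        diag = Kii.diagonal()
        diag[diag == 0] = 1.0
        M = sp.diags(1.0 / diag)
        it_count = [0]

        def cb(_):
            it_count[0] += 1

        ui, info = spla.cg(Kii, f, rtol=tol, atol=0.0, maxiter=max_iter,
                           M=M, callback=cb)
        n_it = it_count[0]
        if info != 0:
            raise SolverError(
                f"CG did not converge for case {case.name}: info={info}, "
                f"residual={np.linalg.norm(Kii @ ui - f) / np.linalg.norm(f):.3e}")
        u[~bmask] = ui
        res = float(np.linalg.norm(Kii @ ui - f) / max(np.linalg.norm(f), 1e-300))
    else:
        res = 0.0
    avg = _average_stress(mesh, D, u)
    return CaseSolution(displacements=u.reshape(-1, 3), average_stress=avg,
                        case=case, n_iterations=n_it, residual=res)


def homogenized_stiffness(
    volume: VoxelVolume,
    material: MaterialModel = MaterialModel(),
    mode: str = "tet",
    tol: float = 1e-8,
) -> StiffnessTensor:
    """Apparent 6x6 stiffness of the RVE from the six canonical KUBC
    probes; symmetrized as (C + C')/2 with the asymmetry norm logged."""
    mesh = voxels_to_elements(volume, mode=mode)
    D = isotropic_stiffness(material)
    K = _assemble(mesh, D)
    C = np.zeros((6, 6))
    for j, case in enumerate(canonical_load_cases()):
        sol = solve_case(mesh, material, case, tol=tol, _K=K)
        s = sol.average_stress
        C[:, j] = [s[0, 0], s[1, 1], s[2, 2], s[1, 2], s[0, 2], s[0, 1]]
    asym = np.abs(C - C.T).max() / max(np.abs(C).max(), 1e-300)
    log.info("stiffness asymmetry |C-C'|/|C| = %.3e", asym)
    return StiffnessTensor(c=0.5 * (C + C.T), basis="lab")


# ---------------------------------------------------------------------------
# fabric rotation and orthotropic projection


def _voigt_to_tensor(c: np.ndarray) -> np.ndarray:
    idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    T = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(idx):
        for J, (k, l) in enumerate(idx):
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = c[I, J]
    return T


def _tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    c = np.zeros((6, 6))
    for I, (i, j) in enumerate(idx):
        for J, (k, l) in enumerate(idx):
            c[I, J] = T[i, j, k, l]
    return c


_ORTHOTROPIC_MASK = np.zeros((6, 6), dtype=bool)
_ORTHOTROPIC_MASK[:3, :3] = True
_ORTHOTROPIC_MASK[3, 3] = _ORTHOTROPIC_MASK[4, 4] = _ORTHOTROPIC_MASK[5, 5] = True


def rotate_to_fabric(
    C: StiffnessTensor,
    fabric_axes: np.ndarray,
    project_orthotropic: bool = True,
) -> tuple[StiffnessTensor, float]:
    """Rotate the stiffness into the fabric frame and optionally project
    onto the orthotropic pattern (nine constants, zero couplings).

    ``fabric_axes`` columns are the fabric directions expressed in the lab
    frame (orthonormal, right-handed). Returns the rotated (projected)
    tensor and the Frobenius norm of the discarded coupling part.
    """
    R = np.asarray(fabric_axes, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("fabric axes must form a 3x3 orthonormal matrix")
    if np.linalg.det(R) < 0:
        raise ValueError("fabric axes must be right-handed")
    T = _voigt_to_tensor(C.c)
    # components in the fabric basis: C'_abcd = R_ia R_jb R_kc R_ld C_ijkl
    Tr = np.einsum("ia,jb,kc,ld,ijkl->abcd", R, R, R, R, T, optimize=True)
    cr = _tensor_to_voigt(Tr)
    if not project_orthotropic:
        return StiffnessTensor(c=cr, basis="fabric"), 0.0
    discarded = np.linalg.norm(cr[~_ORTHOTROPIC_MASK])
    out = np.where(_ORTHOTROPIC_MASK, cr, 0.0)
    return StiffnessTensor(c=out, basis="fabric"), float(discarded)


def orthotropic_constants(C: StiffnessTensor) -> dict[str, float]:
    """The nine orthotropic constants C11, C22, C33, C12, C13, C23,
    C44, C55, C66 (shears in Voigt order 23, 13, 12)."""
    c = C.c
    return {
        "C11": c[0, 0], "C22": c[1, 1], "C33": c[2, 2],
        "C12": c[0, 1], "C13": c[0, 2], "C23": c[1, 2],
        "C44": c[3, 3], "C55": c[4, 4], "C66": c[5, 5],
    }
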
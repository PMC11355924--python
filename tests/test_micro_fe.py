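"""Voxel FE homogenization: meshing arithmetic, solid-material identities,
porosity monotonicity and fabric-frame rotation."""

import numpy as np
import pytest

import osteocurv.micro_fe as fe
from osteocurv.microstructure import (GeneratorSpec, VoxelVolume,
                                      generate_grf_cube, make_primitive)

MAT = fe.MaterialModel()  # 15 GPa, 0.3


@pytest.fixture(scope="module")
def grf32():
    return generate_grf_cube(GeneratorSpec(shape=(32,) * 3, target_bvtv=0.4,
                                           correlation_length=3.5, seed=5))


@pytest.fixture(scope="module")
def grf32_stiffness(grf32):
    return fe.homogenized_stiffness(grf32, MAT, tol=1e-8)


class TestMaterialModel:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            fe.MaterialModel(youngs_modulus=-1.0)
        with pytest.raises(ValueError):
            fe.MaterialModel(poisson_ratio=0.5)


class TestMeshing:
    def test_one_voxel_six_tets_eight_nodes(self):
        data = np.zeros((2, 2, 2), dtype=bool)
        data[0, 0, 0] = True
        mesh = fe.voxels_to_elements(VoxelVolume(data))
        assert mesh.n_elements == 6
        assert mesh.n_nodes == 8

    def test_two_voxels_share_a_face(self):
        data = np.zeros((3, 2, 2), dtype=bool)
        data[0:2, 0, 0] = True
        mesh = fe.voxels_to_elements(VoxelVolume(data))
        assert mesh.n_elements == 12
        assert mesh.n_nodes == 12

    def test_solid_element_count(self):
        mesh = fe.voxels_to_elements(make_primitive("solid", shape=(8,) * 3))
        assert mesh.n_elements == 6 * 8 ** 3
        hexm = fe.voxels_to_elements(make_primitive("solid", shape=(8,) * 3),
                                     mode="hex")
        assert hexm.n_elements == 8 ** 3

    def test_floating_fragment_removed_and_counted(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[0:4, 0:4, 0:4] = True
        data[6, 6, 6] = True  # disconnected voxel
        mesh = fe.voxels_to_elements(VoxelVolume(data))
        assert mesh.n_removed_components == 1
        assert mesh.n_elements == 6 * 64

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError):
            fe.voxels_to_elements(VoxelVolume(np.zeros((4,) * 3, bool)))


class TestSolidIdentities:
    def test_solid_cube_reproduces_isotropic_stiffness(self):
        solid = make_primitive("solid", shape=(8,) * 3, spacing=0.035)
        C = fe.homogenized_stiffness(solid, MAT)
        np.testing.assert_allclose(C.c, fe.isotropic_stiffness(MAT),
                                   atol=1e-10)

    def test_affine_case_is_exact_with_zero_iterations_or_few(self):
        # homogeneous material + affine BC: the affine field solves the
        # problem exactly, so CG converges immediately
        solid = make_primitive("solid", shape=(6,) * 3, spacing=0.035)
        mesh = fe.voxels_to_elements(solid)
        case = fe.canonical_load_cases()[0]
        sol = fe.solve_case(mesh, MAT, case)
        expected = mesh.node_coords @ case.strain.T
        np.testing.assert_allclose(sol.displacements, expected, atol=1e-8)

    def test_zero_strain_gives_zero(self):
        solid = make_primitive("solid", shape=(6,) * 3, spacing=0.035)
        mesh = fe.voxels_to_elements(solid)
        case = fe.LoadCase("null", np.zeros((3, 3)))
        sol = fe.solve_case(mesh, MAT, case)
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.average_stress).max() == 0.0

    def test_hex_mode_matches_closed_form(self):
        solid = make_primitive("solid", shape=(8,) * 3, spacing=0.035)
        C = fe.homogenized_stiffness(solid, MAT, mode="hex")
        np.testing.assert_allclose(C.c, fe.isotropic_stiffness(MAT),
                                   atol=1e-10)


class TestPorousProperties:
    def test_symmetry(self, grf32_stiffness):
        C = grf32_stiffness.c
        assert np.abs(C - C.T).max() / np.abs(C).max() <= 1e-6

    def test_porous_diagonal_below_solid(self, grf32_stiffness):
        solid = np.diag(fe.isotropic_stiffness(MAT))
        assert (np.diag(grf32_stiffness.c) < solid).all()

    def test_stiffness_monotone_in_bvtv(self):
        lo = generate_grf_cube(GeneratorSpec(shape=(24,) * 3, target_bvtv=0.2,
                                             correlation_length=2.5, seed=9))
        hi = generate_grf_cube(GeneratorSpec(shape=(24,) * 3, target_bvtv=0.4,
                                             correlation_length=2.5, seed=9))
        Clo = fe.homogenized_stiffness(lo, MAT, tol=1e-6)
        Chi = fe.homogenized_stiffness(hi, MAT, tol=1e-6)
        assert Chi.c[0, 0] > Clo.c[0, 0]

    def test_linearity_in_tissue_modulus(self):
        vol = generate_grf_cube(GeneratorSpec(shape=(16,) * 3, target_bvtv=0.4,
                                              correlation_length=2.5, seed=3))
        C1 = fe.homogenized_stiffness(vol, fe.MaterialModel(15.0, 0.3),
                                      tol=1e-10)
        C2 = fe.homogenized_stiffness(vol, fe.MaterialModel(30.0, 0.3),
                                      tol=1e-10)
        np.testing.assert_allclose(C2.c, 2.0 * C1.c, rtol=1e-5)

    def test_hex_and_tet_agree(self, grf32, grf32_stiffness):
        Chex = fe.homogenized_stiffness(grf32, MAT, mode="hex", tol=1e-8)
        rel = np.abs(np.diag(grf32_stiffness.c) - np.diag(Chex.c)) \
            / np.diag(Chex.c)
        assert rel.max() < 0.05


class TestFabricRotation:
    def test_identity_rotation_preserves_orthotropic(self, grf32_stiffness):
        out, discarded = fe.rotate_to_fabric(grf32_stiffness, np.eye(3))
        sym = 0.5 * (grf32_stiffness.c + grf32_stiffness.c.T)
        np.testing.assert_allclose(np.diag(out.c), np.diag(sym), rtol=1e-10)

    def test_isotropic_invariant_under_any_rotation(self):
        iso = fe.StiffnessTensor(fe.isotropic_stiffness(MAT))
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        out, discarded = fe.rotate_to_fabric(iso, q,
                                             project_orthotropic=False)
        np.testing.assert_allclose(out.c, iso.c, atol=1e-10)

    def test_rotate_then_back_recovers_constants(self):
        # layered-plate (transversely isotropic) fixture rotated 45 deg and
        # recovered through its known symmetry axes
        plates = make_primitive("plate_lattice", shape=(32,) * 3,
                                spacing=0.035, n_plates=4, thickness=3,
                                gap=5)
        C = fe.homogenized_stiffness(plates, MAT, tol=1e-8)
        ang = np.deg2rad(45)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated, _ = fe.rotate_to_fabric(C, R, project_orthotropic=False)
        back, _ = fe.rotate_to_fabric(rotated, R.T, project_orthotropic=True)
        c0 = fe.orthotropic_constants(fe.StiffnessTensor(0.5 * (C.c + C.c.T)))
        c1 = fe.orthotropic_constants(back)
        for key in c0:
            assert c1[key] == pytest.approx(c0[key], rel=0.02, abs=1e-9)

    def test_non_orthonormal_axes_rejected(self, grf32_stiffness):
        with pytest.raises(ValueError):
            fe.rotate_to_fabric(grf32_stiffness, np.eye(3) * 2.0)
        flipped = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            fe.rotate_to_fabric(grf32_stiffness, flipped)


def test_engineering_constants_of_isotropic():
    iso = fe.StiffnessTensor(fe.isotropic_stiffness(MAT))
    consts = iso.engineering_constants()
    assert consts["E1"] == pytest.approx(15.0)
    assert consts["nu12"] == pytest.approx(0.3)
    assert consts["G12"] == pytest.approx(15.0 / (2 * 1.3))
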
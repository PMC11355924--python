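"""Curvature projection images and probability distributions."""

import numpy as np
import pytest
import trimesh

from osteocurv.curvature import CurvatureField, derived_curvatures
from osteocurv.microstructure import VoxelVolume
from osteocurv.projection import (count_layers, curvature_distribution,
                                  project_curvature, projection_stack)


def _volume(shape=(64, 64, 64), spacing=0.035):
    data = np.zeros(shape, dtype=bool)
    data[1, 1, 1] = True  # content is irrelevant to binning
    return VoxelVolume(data, spacing=spacing)


def _point_mesh(points):
    """Mesh whose vertices sit at given physical positions (one degenerate
    use of a triangle fan; faces are irrelevant for binning)."""
    points = np.asarray(points, dtype=float)
    while len(points) < 3:
        points = np.vstack([points, points[-1] + 1e-5])
    faces = [[0, 1, 2]]
    return trimesh.Trimesh(points, faces, process=False)


class TestCountLayers:
    def test_six_mm_cube_has_172_layers(self):
        vol = VoxelVolume(np.zeros((172, 4, 4), dtype=bool) | True,
                          spacing=0.035)
        assert count_layers(vol, axis=0) == 172

    def test_voxel_count_at_any_spacing(self):
        vol = _volume((64, 32, 16), spacing=0.123)
        assert [count_layers(vol, a) for a in (0, 1, 2)] == [64, 32, 16]

    def test_fractional_extent(self):
        vol = _volume((4, 4, 4), spacing=0.25)
        assert count_layers(vol, 2) == 4


class TestProjectCurvature:
    def test_single_vertex_oracle(self):
        vol = _volume()
        sp = vol.spacing
        # place the carrying vertex inside bin (10, 12); helpers in (0, 0)
        mesh = _point_mesh([[10.5 * sp, 12.5 * sp, 0.5],
                            [0.2 * sp, 0.2 * sp, 0.5],
                            [0.4 * sp, 0.3 * sp, 0.5]])
        values = np.array([3.0, 0.0, 0.0])
        img = project_curvature(mesh, values, "k1", vol, axis=2)
        assert img.n_layers == 64
        assert img.pixels[10, 12] == pytest.approx(3.0 / 64)
        nonzero = np.argwhere(img.pixels != 0)
        assert nonzero.tolist() == [[0, 0], [10, 12]] or \
            img.pixels[0, 0] == 0  # helper vertices carry zero curvature

    def test_opposite_curvatures_cancel(self):
        vol = _volume()
        sp = vol.spacing
        mesh = _point_mesh([[10.2 * sp, 12.2 * sp, 0.5],
                            [10.8 * sp, 12.8 * sp, 0.6],
                            [0.5 * sp, 0.5 * sp, 0.5]])
        img = project_curvature(mesh, np.array([2.5, -2.5, 0.0]), "mean",
                                vol, axis=2)
        assert img.pixels[10, 12] == 0.0
        assert not img.pixels.any()

    def test_empty_bins_are_exact_zero(self):
        vol = _volume()
        mesh = _point_mesh([[0.01, 0.01, 0.5]])
        img = project_curvature(mesh, np.zeros(3), "k1", vol)
        assert (img.pixels == 0).all()

    def test_boundary_vertex_goes_to_higher_bin(self):
        vol = _volume((8, 8, 8), spacing=0.5)
        mesh = _point_mesh([[1.0, 1.0, 1.0]])  # exactly on bin edge 2
        img = project_curvature(mesh, np.array([1.0, 0, 0]), "k1", vol)
        assert img.pixels[2, 2] != 0

    def test_far_outside_vertex_raises(self):
        vol = _volume((8, 8, 8), spacing=0.5)
        mesh = _point_mesh([[40.0, 1.0, 1.0]])
        with pytest.raises(IndexError, match="vertex 0"):
            project_curvature(mesh, np.array([1.0, 0, 0]), "k1", vol)

    def test_linearity_and_conservation(self, vox_sphere_volume,
                                        vox_sphere_mesh, vox_sphere_field):
        vol, mesh, f = vox_sphere_volume, vox_sphere_mesh, vox_sphere_field
        a = project_curvature(mesh, f.k1, "k1", vol).pixels
        b = project_curvature(mesh, f.k2, "k1", vol).pixels
        combo = project_curvature(mesh, 2.0 * f.k1 - 0.5 * f.k2, "k1",
                                  vol).pixels
        np.testing.assert_allclose(combo, 2.0 * a - 0.5 * b, rtol=1e-9,
                                   atol=1e-12)
        n = count_layers(vol, 2)
        assert a.sum() * n == pytest.approx(f.k1.sum(), rel=1e-9)

    def test_invariant_to_vertex_ordering(self, vox_sphere_volume,
                                          vox_sphere_mesh, vox_sphere_field):
        vol, mesh, f = vox_sphere_volume, vox_sphere_mesh, vox_sphere_field
        base = project_curvature(mesh, f.mean, "mean", vol).pixels
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(mesh.vertices))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = trimesh.Trimesh(mesh.vertices[perm], inv[mesh.faces],
                                   process=False)
        again = project_curvature(shuffled, f.mean[perm], "mean", vol).pixels
        np.testing.assert_allclose(again, base, rtol=1e-12)


class TestProjectionStack:
    def test_channels_ordered_and_rescaled(self, vox_sphere_volume,
                                           vox_sphere_mesh,
                                           vox_sphere_field):
        stack, ranges = projection_stack(vox_sphere_mesh, vox_sphere_field,
                                         vox_sphere_volume)
        assert stack.shape == (4, 96, 96)
        assert len(ranges) == 4
        assert stack.min() >= 0.0 and stack.max() <= 1.0
        # recorded ranges undo the rescale
        k1 = project_curvature(vox_sphere_mesh, vox_sphere_field, "k1",
                               vox_sphere_volume).pixels
        mn, mx = ranges[0]
        np.testing.assert_allclose(stack[0] * (mx - mn) + mn, k1, atol=1e-12)

    def test_symmetric_range_maps_zero_to_half(self):
        vol = _volume((8, 8, 8), spacing=0.5)
        sp = vol.spacing
        mesh = _point_mesh([[0.25, 0.25, 1], [1.25, 1.25, 1], [2.25, 2.25, 1]])
        f = CurvatureField(k1=[8.0, -8.0, 0.0], k2=[8.0, -8.0, 0.0])
        derived_curvatures(f)
        stack, ranges = projection_stack(mesh, f, vol)
        assert ranges[0] == (-1.0, 1.0)
        assert stack[0][4, 4] == pytest.approx(0.5)  # empty bin, value 0

    def test_constant_channel_warns_and_zeroes(self):
        vol = _volume((8, 8, 8), spacing=0.5)
        mesh = _point_mesh([[0.25, 0.25, 1], [1.25, 1.25, 1], [2.2, 2.2, 1]])
        f = derived_curvatures(CurvatureField(k1=np.zeros(3), k2=np.zeros(3)))
        with pytest.warns(UserWarning, match="constant"):
            stack, _ = projection_stack(mesh, f, vol)
        assert not stack.any()


class TestCurvatureDistribution:
    def test_single_value_single_bin(self):
        f = CurvatureField(k1=np.full(10, 1.0), k2=np.zeros(10))
        h = curvature_distribution(f, "k1", n_bins=5, value_range=(0, 2))
        assert h.probability.sum() == pytest.approx(1.0, abs=1e-9)
        assert h.probability[2] == 1.0

    def test_probabilities_sum_to_one(self, vox_sphere_field):
        h = curvature_distribution(vox_sphere_field, "mean", n_bins=50)
        assert h.probability.sum() == pytest.approx(1.0, abs=1e-9)
        assert (h.probability >= 0).all()

    def test_sphere_mode_contains_analytic_curvature(self, vox_sphere_field):
        h = curvature_distribution(vox_sphere_field, "mean", n_bins=40,
                                   value_range=(0, 2))
        mode = np.argmax(h.probability)
        assert h.bin_edges[mode] <= 1.0 <= h.bin_edges[mode + 1]

    def test_empty_valid_set_raises(self):
        f = CurvatureField(k1=np.ones(4), k2=np.ones(4),
                           valid_mask=np.zeros(4, dtype=bool))
        with pytest.raises(ValueError):
            curvature_distribution(f, "k1")
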
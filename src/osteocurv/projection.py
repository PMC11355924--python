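"""2D projection images and probability distributions of surface curvature.

A curvature field living on the vertices of a trabecular surface mesh is
collapsed along one axis of the voxel grid into a 2D image: the grid's
in-plane voxel lattice defines the pixel bins, every vertex deposits its
curvature value into the bin containing its in-plane position, and each
bin is divided by the number n of one-voxel-thick layers along the
projection direction,

    K(x, y) = (1/n) * sum_z k(x, y, z).

A 6 mm cube at 35 um spacing yields n = 172 layers and a 172 x 172 image.
The four curvature kinds (k1, k2, Gaussian, mean) stack into one 4-channel
image used as CNN input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .curvature import CurvatureField
from .microstructure import VoxelVolume

__all__ = [
    "ProjectionImage",
    "CurvatureHistogram",
    "count_layers",
    "project_curvature",
    "projection_stack",
    "curvature_distribution",
    "CURVATURE_KINDS",
]

CURVATURE_KINDS = ("k1", "k2", "gaussian", "mean")


@dataclass
class ProjectionImage:
    """Projected curvature image. ``pixels[i, j]`` covers the in-plane voxel
    column (i, j); bins receiving no vertices hold exactly 0."""

    pixels: np.ndarray
    axis: int
    curvature_kind: str
    n_layers: int

    @property
    def resolution(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CurvatureHistogram:
    """Normalized curvature distribution: probabilities per bin sum to 1."""

    bin_edges: np.ndarray
    probability: np.ndarray


def count_layers(volume: VoxelVolume, axis: int) -> int:
    """Number of one-voxel-thick layers along the projection axis:
    ceil(physical extent / spacing), i.e. the voxel count for grid-aligned
    volumes (172 for a 6 mm cube at 35 um)."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    extent = volume.extent[axis]
    return int(np.ceil(extent / volume.spacing - 1e-9))


def _inplane_axes(axis: int) -> tuple[int, int]:
    return tuple(a for a in range(3) if a != axis)


def project_curvature(
    mesh: trimesh.Trimesh,
    fieldvals: CurvatureField | np.ndarray,
    curvature_kind: str,
    volume: VoxelVolume,
    axis: int = 2,
    use_valid_mask: bool = False,
) -> ProjectionImage:
    """Project per-vertex curvature values along ``axis`` onto the in-plane
    voxel grid.

    Bins are half-open intervals [edge, next_edge) in physical coordinates,
    so a vertex exactly on a boundary lands in the higher-index bin. All
    vertices are included by default (``use_valid_mask=True`` drops
    cut-plane vertices instead). Vertices more than one voxel outside the
    volume bounds raise an indexing error naming the vertex; the cap
    vertices the padded marching cubes places up to half a voxel outside
    are clamped into the edge bins.
    """
    if curvature_kind not in CURVATURE_KINDS:
        raise ValueError(f"unknown curvature kind {curvature_kind!r}")
    values = (fieldvals.by_kind(curvature_kind)
              if isinstance(fieldvals, CurvatureField) else np.asarray(fieldvals, float))
    V = mesh.vertices.view(np.ndarray)
    if len(values) != len(V):
        raise ValueError("curvature values and mesh vertices disagree in length")
    if use_valid_mask and isinstance(fieldvals, CurvatureField):
        sel = fieldvals.valid_mask
        V, values = V[sel], values[sel]

    n = count_layers(volume, axis)
    a, b = _inplane_axes(axis)
    lo = np.asarray(volume.origin, dtype=float)
    shape = volume.shape
    img = np.zeros((shape[a], shape[b]))
    if len(V):
        rel = (V - lo[None, :]) / volume.spacing
        tol = 1.0  # voxels
        for ax in (a, b):
            bad = (rel[:, ax] < -tol) | (rel[:, ax] > shape[ax] + tol)
            if bad.any():
                raise IndexError(
                    f"vertex {int(np.argmax(bad))} lies outside the volume bounds")
        ia = np.clip(np.floor(rel[:, a]).astype(int), 0, shape[a] - 1)
        ib = np.clip(np.floor(rel[:, b]).astype(int), 0, shape[b] - 1)
        np.add.at(img, (ia, ib), values)
    img /= n
    return ProjectionImage(pixels=img, axis=axis, curvature_kind=curvature_kind,
                           n_layers=n)


def projection_stack(
    mesh: trimesh.Trimesh,
    fieldvals: CurvatureField,
    volume: VoxelVolume,
    axis: int = 2,
    rescale: bool = True,
    use_valid_mask: bool = False,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """4-channel projection image, channels ordered (k1, k2, K, H).

    With ``rescale`` each channel is independently min-max mapped to [0, 1]
    (the recorded per-channel (min, max) allow undoing this); a constant
    channel maps to all zeros with a warning. Returns ``(stack, ranges)``
    with ``stack`` shaped (4, nx, ny).
    """
    channels, ranges = [], []
    for kind in CURVATURE_KINDS:
        img = project_curvature(mesh, fieldvals, kind, volume, axis,
                                use_valid_mask=use_valid_mask).pixels
        mn, mx = float(img.min()), float(img.max())
        ranges.append((mn, mx))
        if rescale:
            if mx > mn:
                img = (img - mn) / (mx - mn)
            else:
                warnings.warn(
                    f"constant {kind} projection channel rescaled to all-zero",
                    stacklevel=2)
                img = np.zeros_like(img)
        channels.append(img)
    return np.stack(channels), ranges


def curvature_distribution(
    fieldvals: CurvatureField,
    curvature_kind: str,
    n_bins: int = 100,
    value_range: tuple[float, float] | None = None,
) -> CurvatureHistogram:
    """Probability distribution of a curvature kind over valid vertices."""
    values = fieldvals.by_kind(curvature_kind)[fieldvals.valid_mask]
    if len(values) == 0:
        raise ValueError("no valid vertices to histogram")
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    total = counts.sum()
    if total == 0:
        raise ValueError("all vertices fall outside the histogram range")
    return CurvatureHistogram(bin_edges=edges, probability=counts / total)
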
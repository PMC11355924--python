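"""Individual-trabecula decomposition into plates and rods.

Trabecular bone is a mixture of sheet-like (plate) and strut-like (rod)
elements. This module provides a deliberately simplified decomposition:

1. the foreground is thinned to a one-voxel skeleton by iterative removal
   of simple points (removal that preserves local topology) in six
   directional subiterations — sheets thin to medial surfaces, struts to
   medial curves;
2. each skeleton voxel is classified surface-type (plate) or curve-type
   (rod) from its 26-neighborhood skeleton degree;
3. connected same-class skeleton segments become individual trabeculae and
   every bone voxel inherits the label of its nearest skeleton voxel.

Per-trabecula measurements then give the eight summary metrics: plate and
rod counts (PN, RN), mean plate area/thickness (PA, PT), mean rod
diameter/length (RD, RL) and the mean same-class nearest-neighbor centroid
distances (NND_PP, NND_RR). This is a surrogate for full individual
trabecula segmentation, validated on fixtures with known composition, and
makes no bit-compatibility claim against any reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.spatial import cKDTree

from .histomorphometry import local_thickness_map
from .microstructure import STRUCT_26, VoxelVolume

__all__ = [
    "PlateRodMetrics",
    "PlateRodDecomposition",
    "skeletonize",
    "decompose",
    "measure",
]


@dataclass(frozen=True)
class PlateRodMetrics:
    """Summary metrics; means are NaN when the corresponding count is 0."""

    pn: int
    rn: int
    pa: float
    pt: float
    rd: float
    rl: float
    nnd_pp: float
    nnd_rr: float

    names = ("pn", "rn", "pa", "pt", "rd", "rl", "nnd_pp", "nnd_rr")

    def as_array(self) -> np.ndarray:
        return np.array([self.pn, self.rn, self.pa, self.pt,
                         self.rd, self.rl, self.nnd_pp, self.nnd_rr])


@dataclass
class PlateRodDecomposition:
    """``labels`` partitions bone voxels (0 = background); ``kinds`` maps
    each label to "plate" or "rod"; ``skeleton`` is the thinned mask."""

    labels: np.ndarray
    kinds: dict[int, str]
    skeleton: np.ndarray

    @property
    def plate_labels(self) -> list[int]:
        return [k for k, v in self.kinds.items() if v == "plate"]

    @property
    def rod_labels(self) -> list[int]:
        return [k for k, v in self.kinds.items() if v == "rod"]


@njit(cache=True)
def _neighbor_block(img, x, y, z, out):
    for i in range(3):
        for j in range(3):
            for k in range(3):
                out[i, j, k] = img[x + i - 1, y + j - 1, z + k - 1]


@njit(cache=True)
def _is_simple(nb):
    """Simple-point test on a 3x3x3 neighborhood (center assumed True).

    The center may be deleted without changing local topology iff the
    foreground in the 26-neighborhood (center excluded) forms exactly one
    26-connected component, and the background 6-neighbors of the center
    belong to exactly one 6-connected background component within the
    18-neighborhood.
    """
    # --- foreground 26-components, excluding center ---
    lab = np.zeros(27, dtype=np.int8)
    ncomp = 0
    stack = np.empty(27, dtype=np.int8)
    for s in range(27):
        i, j, k = s // 9, (s // 3) % 3, s % 3
        if (i == 1 and j == 1 and k == 1) or not nb[i, j, k] or lab[s]:
            continue
        ncomp += 1
        if ncomp > 1:
            return False
        top = 0
        stack[top] = s
        top += 1
        lab[s] = 1
        while top > 0:
            top -= 1
            c = stack[top]
            ci, cj, ck = c // 9, (c // 3) % 3, c % 3
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    for dk in range(-1, 2):
                        ni, nj, nk = ci + di, cj + dj, ck + dk
                        if ni < 0 or ni > 2 or nj < 0 or nj > 2 or nk < 0 or nk > 2:
                            continue
                        if ni == 1 and nj == 1 and nk == 1:
                            continue
                        t = ni * 9 + nj * 3 + nk
                        if nb[ni, nj, nk] and not lab[t]:
                            lab[t] = 1
                            stack[top] = t
                            top += 1
    if ncomp != 1:
        return False

    # --- background 6-components in N18 that touch a 6-neighbor of center ---
    lab2 = np.zeros(27, dtype=np.int8)
    ncomp2 = 0
    for s in range(27):
        i, j, k = s // 9, (s // 3) % 3, s % 3
        d = abs(i - 1) + abs(j - 1) + abs(k - 1)
        if d != 1 or nb[i, j, k] or lab2[s]:
            continue  # seeds are background 6-neighbors of center
        ncomp2 += 1
        if ncomp2 > 1:
            return False
        top = 0
        stack[top] = s
        top += 1
        lab2[s] = 1
        while top > 0:
            top -= 1
            c = stack[top]
            ci, cj, ck = c // 9, (c // 3) % 3, c % 3
            for a in range(6):
                di = (1, -1, 0, 0, 0, 0)[a]
                dj = (0, 0, 1, -1, 0, 0)[a]
                dk = (0, 0, 0, 0, 1, -1)[a]
                ni, nj, nk = ci + di, cj + dj, ck + dk
                if ni < 0 or ni > 2 or nj < 0 or nj > 2 or nk < 0 or nk > 2:
                    continue
                dd = abs(ni - 1) + abs(nj - 1) + abs(nk - 1)
                if dd == 0 or dd > 2:
                    continue  # stay inside the 18-neighborhood
                t = ni * 9 + nj * 3 + nk
                if not nb[ni, nj, nk] and not lab2[t]:
                    lab2[t] = 1
                    stack[top] = t
                    top += 1
    return ncomp2 == 1


@njit(cache=True)
def _count_neighbors(img, x, y, z):
    n = 0
    for di in range(-1, 2):
        for dj in range(-1, 2):
            for dk in range(-1, 2):
                if di == 0 and dj == 0 and dk == 0:
                    continue
                if img[x + di, y + dj, z + dk]:
                    n += 1
    return n


@njit(cache=True)
def _thin_pass(img, cand, order):
    """Sequentially delete candidate voxels that remain simple and are not
    curve endpoints. Returns the number deleted."""
    removed = 0
    nb = np.empty((3, 3, 3), dtype=np.bool_)
    for idx in order:
        x, y, z = cand[idx]
        if not img[x, y, z]:
            continue
        n = _count_neighbors(img, x, y, z)
        if n <= 2:
            # isolated voxels, curve endpoints, and the moving front of a
            # near-line region: protecting degree <= 2 stops a sequential
            # pass from consuming a two-wide ribbon end-to-end
            continue
        _neighbor_block(img, x, y, z, nb)
        if _is_simple(nb):
            img[x, y, z] = False
            removed += 1
    return removed


_DIRECTIONS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a one-voxel-wide curve skeleton.

    Border voxels are visited in six directional subiterations (up, down,
    north, south, east, west) and removed when they are simple points
    (their removal preserves local topology) and not curve endpoints.
    """
    if not mask.any():
        raise ValueError("cannot skeletonize an empty volume")
    img = np.pad(mask.astype(bool), 1)
    while True:
        removed = 0
        for d in _DIRECTIONS:
            border = img & ~np.roll(img, tuple(d), axis=(0, 1, 2))
            cand = np.argwhere(border)
            if len(cand) == 0:
                continue
            removed += _thin_pass(img, cand, np.arange(len(cand)))
        if removed == 0:
            break
    return img[1:-1, 1:-1, 1:-1]


def _classify_skeleton(
    skel: np.ndarray,
    data: np.ndarray,
    thickness_vox: np.ndarray,
    radius_factor: float = 1.5,
    min_radius: float = 3.0,
    max_radius: float = 9.0,
    planarity_threshold: float = 0.4,
) -> np.ndarray:
    """Per-skeleton-voxel class: 1 = curve-type (rod), 2 = surface-type
    (plate).

    Each skeleton voxel is classified from the shape of the *bone* voxel
    cloud within an adaptive radius (``radius_factor`` x the local
    thickness): principal-component variances l1 >= l2 >= l3 of that cloud
    are ~1D around a rod (l2/l1 small) and ~2D inside a plate (l2/l1
    near 1). The ratio threshold separates the two.
    """
    pts = np.argwhere(skel)
    out = np.zeros(skel.shape, dtype=np.uint8)
    if len(pts) == 0:
        return out
    bone_pts = np.argwhere(data).astype(float)
    tree = cKDTree(bone_pts)
    radii = np.clip(radius_factor * thickness_vox[pts[:, 0], pts[:, 1], pts[:, 2]],
                    min_radius, max_radius)
    cls = np.ones(len(pts), dtype=np.uint8)
    for i, (p, r) in enumerate(zip(pts.astype(float), radii)):
        nb = tree.query_ball_point(p, r=r)
        if len(nb) < 6:
            continue
        local = bone_pts[nb] - bone_pts[nb].mean(axis=0)
        cov = local.T @ local
        evals = np.linalg.eigvalsh(cov)
        if evals[2] > 0 and evals[1] / evals[2] >= planarity_threshold:
            cls[i] = 2
    out[pts[:, 0], pts[:, 1], pts[:, 2]] = cls
    return out


def decompose(
    volume: VoxelVolume,
    min_segment_voxels: int = 5,
    split_at_junctions: bool = True,
) -> PlateRodDecomposition:
    """Label every bone voxel as belonging to an individual plate or rod.

    The curve skeleton is split into segments at junction voxels
    (skeleton degree >= 3) so each branch of the network becomes its own
    trabecula; segments smaller than ``min_segment_voxels`` are treated as
    spur artifacts and absorbed into the nearest surviving segment.
    """
    data = volume.data
    if not data.any():
        raise ValueError("cannot decompose an empty volume")
    skel = skeletonize(data)
    thickness_vox = local_thickness_map(volume) / volume.spacing
    classes = _classify_skeleton(skel, data, thickness_vox)

    seg_mask = skel.copy()
    if split_at_junctions:
        padded = np.pad(skel, 1)
        kernel = np.ones((3, 3, 3), dtype=np.uint8)
        kernel[1, 1, 1] = 0
        degree = ndimage.convolve(padded.astype(np.uint8), kernel,
                                  mode="constant")[1:-1, 1:-1, 1:-1]
        # split only rod-class junctions: a branched skeleton inside one
        # plate must stay a single trabecula
        junctions = skel & (degree >= 3) & (classes == 1)
        if (seg_mask & ~junctions).any():
            seg_mask = seg_mask & ~junctions

    labels = np.zeros(data.shape, dtype=np.int32)
    kinds: dict[int, str] = {}
    nxt = 1
    for cls, name in ((2, "plate"), (1, "rod")):
        lab, n = ndimage.label(seg_mask & (classes == cls), structure=STRUCT_26)
        for i in range(1, n + 1):
            labels[lab == i] = nxt
            kinds[nxt] = name
            nxt += 1

    # absorb small skeleton segments into the nearest big one
    sizes = np.bincount(labels.ravel(), minlength=nxt)
    small = [k for k in kinds if sizes[k] < min_segment_voxels]
    if small and len(small) < len(kinds):
        small_mask = np.isin(labels, small)
        big_mask = (labels > 0) & ~small_mask
        _, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~big_mask, return_indices=True)
        labels[small_mask] = labels[ix[small_mask], iy[small_mask], iz[small_mask]]
        for k in small:
            kinds.pop(k)

    # propagate skeleton labels to all bone voxels (nearest skeleton voxel)
    skel_mask = labels > 0
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~skel_mask, return_indices=True)
    full = np.zeros_like(labels)
    full[data] = labels[ix[data], iy[data], iz[data]]
    return PlateRodDecomposition(labels=full, kinds=kinds, skeleton=skel)


def _segment_length(points: np.ndarray, spacing: float) -> float:
    """Axis extent of a curve segment: distance between the extreme
    projections onto the principal axis of its voxel cloud (exact for
    straight rods, a lower bound for strongly curved ones)."""
    if len(points) == 1:
        return spacing
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt[0]
    return float((proj.max() - proj.min()) * spacing)


def measure(
    decomposition: PlateRodDecomposition,
    volume: VoxelVolume,
    thickness_map: np.ndarray | None = None,
) -> PlateRodMetrics:
    """Eight summary metrics from a labeled decomposition.

    Per plate: thickness = mean local thickness over its voxels, area =
    voxel volume / thickness. Per rod: diameter = mean local thickness,
    length = skeleton arc length. NND = mean over trabeculae of the
    centroid distance to the nearest same-class trabecula.
    """
    sp = volume.spacing
    if thickness_map is None:
        thickness_map = local_thickness_map(volume)
    labels = decomposition.labels
    vox_vol = sp ** 3

    plate_areas, plate_thicks, plate_cents = [], [], []
    rod_diams, rod_lens, rod_cents = [], [], []
    for lbl, kind in decomposition.kinds.items():
        sel = labels == lbl
        nvox = int(sel.sum())
        if nvox == 0:
            continue
        cent = np.argwhere(sel).mean(axis=0) * sp
        thick = float(thickness_map[sel].mean())
        if kind == "plate":
            plate_thicks.append(thick)
            plate_areas.append(nvox * vox_vol / thick)
            plate_cents.append(cent)
        else:
            rod_diams.append(thick)
            skel_pts = np.argwhere(decomposition.skeleton & sel)
            if len(skel_pts) == 0:
                skel_pts = np.argwhere(sel)
            # the medial axis stops one inscribed radius short of each rod
            # end, so the full rod length is the axis extent plus the
            # diameter
            rod_lens.append(_segment_length(skel_pts.astype(float), sp) + thick)
            rod_cents.append(cent)

    def _nnd(cents: list[np.ndarray]) -> float:
        if len(cents) < 2:
            return float("nan")
        pts = np.asarray(cents)
        d, _ = cKDTree(pts).query(pts, k=2)
        return float(d[:, 1].mean())

    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return PlateRodMetrics(
        pn=len(plate_areas), rn=len(rod_diams),
        pa=mean(plate_areas), pt=mean(plate_thicks),
        rd=mean(rod_diams), rl=mean(rod_lens),
        nnd_pp=_nnd(plate_cents), nnd_rr=_nnd(rod_cents),
    )
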
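"""Starting-point extraction from a membrane mask.

A membrane score map (or binary mask) is post-processed into a clean binary
mask, its single-voxel boundary is extracted, user seed points are extended
along the boundary into chains with monotone coordinates, and statistical
outliers are removed with the mean-kNN-distance rule familiar from
point-cloud processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import feature, measure

from .volio import PointSet, VoxelVolume

__all__ = [
    "SeedPoint",
    "ExtractParams",
    "postprocess_mask",
    "extract_boundary",
    "extend_from_seed",
    "extract_starting_points",
    "remove_outliers",
]

# Axis permutation (new_from_old) per seed perpendicular axis.  The extension
# algorithm is written for a membrane roughly perpendicular to X; the Y case
# swaps X and Y, the Z case swaps X and Z.
_PERM = {"X": (0, 1, 2), "Y": (1, 0, 2), "Z": (2, 1, 0)}


@dataclass
class SeedPoint:
    """A user-marked voxel on the membrane boundary.

    ``perp_axis`` names the raw axis most perpendicular to the membrane.
    """

    position: np.ndarray
    perp_axis: str = "X"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.perp_axis not in _PERM:
            raise ValueError(f"perp_axis must be one of X/Y/Z, got {self.perp_axis!r}")


@dataclass
class ExtractParams:
    boundary_method: str = "erosion"
    max_extent_primary: int = 10_000
    max_extent_secondary: int = 10_000
    knn: int = 50
    nsd: float = 2.0

    def __post_init__(self) -> None:
        if self.max_extent_primary < 0 or self.max_extent_secondary < 0:
            raise ValueError("max extents must be >= 0")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if not self.nsd > 0:
            raise ValueError("nsd must be > 0")


def postprocess_mask(
    scores: VoxelVolume,
    sigma: float = 0.0,
    threshold: float = 0.5,
    min_2d: int = 1,
    min_3d: int = 1,
) -> VoxelVolume:
    """Turn a membrane score map into a clean binary mask.

    Gaussian filtering, thresholding, then small-connected-component removal:
    first 2D per X-Y slice (8-connectivity), then 3D (26-connectivity).
    """
    data = np.asarray(scores.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("score map contains non-finite values")
    if sigma > 0:
        data = ndimage.gaussian_filter(data, sigma)
    mask = data > threshold

    if min_2d > 1:
        for z in range(mask.shape[2]):
            sl = mask[:, :, z]
            if not sl.any():
                continue
            lab = measure.label(sl, connectivity=2)
            counts = np.bincount(lab.ravel())
            small = np.flatnonzero(counts < min_2d)
            sl[np.isin(lab, small[small != 0])] = False
    if min_3d > 1 and mask.any():
        lab = measure.label(mask, connectivity=3)
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_3d)
        mask[np.isin(lab, small[small != 0])] = False

    if not mask.any():
        warnings.warn("postprocess_mask produced an empty mask", stacklevel=2)
    return VoxelVolume(mask.astype(np.float32), voxel_size=scores.voxel_size, origin=scores.origin)


_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connected


def extract_boundary(mask: VoxelVolume, method: str = "erosion") -> VoxelVolume:
    """Extract a single-voxel-thick boundary from a binary mask.

    ``erosion``: boundary = mask minus its 6-connected binary erosion (the
    eroded-away shell).  ``canny``: union over X-Y slices of 2D Canny edges.
    """
    m = np.asarray(mask.data) > 0.5
    if method == "erosion":
        boundary = m & ~ndimage.binary_erosion(m, structure=_CROSS)
    elif method == "canny":
        boundary = np.zeros_like(m)
        for z in range(m.shape[2]):
            sl = m[:, :, z]
            if sl.any():
                boundary[:, :, z] = feature.canny(sl.astype(float), sigma=1.0)
    else:
        raise ValueError(f"unknown boundary method {method!r} (use 'erosion' or 'canny')")
    return VoxelVolume(boundary.astype(np.float32), voxel_size=mask.voxel_size, origin=mask.origin)


def _walk_line(occ: np.ndarray, start_a: int, fixed_b: int, start_c: int,
               step: int, max_steps: int, axis_order: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Walk along the boundary stepping coordinate ``c`` by ``step``.

    ``occ`` is the boundary indexed in permuted axes (a, b, c); ``a`` is the
    membrane-perpendicular axis (the chain's lateral coordinate), ``b`` is held
    fixed, ``c`` increases/decreases monotonically by construction.  At each
    step the candidate voxels are those at c+step with |a - a_prev| <= 2;
    nearest lateral offset wins, ties broken by smaller offset then smaller
    coordinate.  The walk stops when no candidate exists or max_steps reached.
    """
    na, _, nc = occ.shape
    out = []
    a, c = start_a, start_c
    for _ in range(max_steps):
        c2 = c + step
        if not (0 <= c2 < nc):
            break
        lo, hi = max(0, a - 2), min(na, a + 3)
        cands = np.flatnonzero(occ[lo:hi, fixed_b, c2]) + lo
        if cands.size == 0:
            break
        off = np.abs(cands - a)
        best = cands[np.lexsort((cands, off))][0]
        a, c = int(best), c2
        out.append((a, fixed_b, c))
    return out


def extend_from_seed(boundary: VoxelVolume, seed: SeedPoint, params: ExtractParams) -> PointSet:
    """Extend one seed along the boundary into starting points.

    For a membrane perpendicular to X: the primary chain lives in the seed's
    x-z plane and steps Z by +-1 (Z strictly monotone per direction); from
    every primary-chain point a secondary chain steps Y by +-1 within its x-y
    plane.  Other perpendicular axes are handled by axis permutation.
    """
    perm = _PERM[seed.perp_axis]
    occ = np.transpose(np.asarray(boundary.data) > 0.5, perm)
    pos = seed.position[list(perm)]
    idx = np.round(pos).astype(int)
    if np.any(idx < 0) or np.any(idx >= occ.shape):
        raise ValueError(f"seed {seed.position} outside volume bounds")

    if not occ[tuple(idx)]:
        # snap within a 1-voxel Chebyshev ball, else report the nearest boundary voxel
        lo = np.maximum(idx - 1, 0)
        hi = np.minimum(idx + 2, occ.shape)
        patch = occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        hits = np.argwhere(patch)
        if hits.size:
            d = np.linalg.norm(hits + lo - pos, axis=1)
            idx = hits[np.argmin(d)] + lo
        else:
            allb = np.argwhere(occ)
            if allb.size == 0:
                raise ValueError("seed off boundary: boundary is empty")
            nearest = allb[np.argmin(np.linalg.norm(allb - pos, axis=1))]
            inv = np.argsort(perm)
            raise ValueError(
                f"seed off boundary; nearest boundary voxel is {tuple(int(v) for v in nearest[inv])}"
            )

    a0, b0, c0 = (int(v) for v in idx)
    primary = [(a0, b0, c0)]
    for step in (+1, -1):
        primary += _walk_line(occ, a0, b0, c0, step, params.max_extent_primary, perm)

    points = set(primary)
    # Secondary chains step the Y (b) coordinate within each primary point's
    # x-y plane (fixed c).  Reuse the walker on an axis-swapped view (a, c, b).
    occ_cb = np.ascontiguousarray(occ.transpose(0, 2, 1))
    for (a, b, c) in primary:
        for step in (+1, -1):
            for (pa, pc, pb) in _walk_line(occ_cb, a, c, b, step,
                                           params.max_extent_secondary, perm):
                points.add((pa, pb, pc))

    inv = np.argsort(perm)
    arr = np.array(sorted(points), dtype=float)[:, inv]
    return PointSet(points=arr, label="starting_points")


def extract_starting_points(boundary: VoxelVolume, seeds: list[SeedPoint],
                            params: ExtractParams) -> PointSet:
    """Run every seed independently, union the chains, then one joint
    outlier-removal pass."""
    all_pts = [extend_from_seed(boundary, s, params).points for s in seeds]
    merged = np.unique(np.vstack(all_pts), axis=0)
    return remove_outliers(PointSet(merged, label="starting_points"),
                           knn=params.knn, nsd=params.nsd)


def remove_outliers(points: PointSet, knn: int = 50, nsd: float = 2.0) -> PointSet:
    """Drop points whose mean k-nearest-neighbor distance is anomalously large.

    A point is an outlier when its average distance to its ``knn`` nearest
    neighbors exceeds the mean plus ``nsd`` standard deviations of those
    averages over all points.  k is clipped to n - 1 for small sets.
    """
    pts = points.points
    n = len(points)
    if n < 2:
        warnings.warn("remove_outliers: fewer than 2 points, returned unchanged", stacklevel=2)
        return points
    k = min(knn, n - 1)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)  # first neighbor is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    keep = mean_d <= mean_d.mean() + nsd * mean_d.std()
    return PointSet(points=pts[keep], label=points.label)
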
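"""Distortion quantification via the first fundamental form.

Flattening maps a small circle on a flattened-tomogram slice to a small
ellipse on the corresponding 3D surface.  The semi-axes sigma_1 >= sigma_2
of that ellipse are the square roots of the eigenvalues of the first
fundamental form [[E, F], [F, G]] built from the numerical tangent vectors
r_u, r_v of the slice surface.  Area distortion is sigma_1 * sigma_2 (the
reciprocal is recorded, flagged as contraction, when it is below 1); shape
distortion is sigma_1 / sigma_2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flattening import FlatMap
from .volio import VoxelVolume, write_volume

__all__ = [
    "DistortionMap",
    "fundamental_form",
    "singular_values",
    "distortion_map",
    "optcuts_energy",
    "write_distortion_maps",
]


@dataclass
class DistortionMap:
    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    area: np.ndarray          # >= 1
    area_sign: np.ndarray     # +1 expansion, -1 contraction
    shape: np.ndarray         # sigma1 / sigma2 >= 1
    edge: np.ndarray          # True where one-sided differences were used
    w: float = 0.0


def _slice_positions(flatmap: FlatMap, w: float) -> np.ndarray:
    return flatmap.S + (w - flatmap.w_c) * flatmap.N


def fundamental_form(flatmap: FlatMap, w: float, uv: tuple[int, int]) -> tuple[float, float, float]:
    """E, F, G at one grid node from the four neighbors (u0 +- 1, v0 +- 1).

    Central differences with step 1 px (halved); one-sided at grid edges.
    """
    u0, v0 = int(uv[0]), int(uv[1])
    nu, nv = flatmap.shape
    if not (0 <= u0 < nu and 0 <= v0 < nv):
        raise ValueError("(u, v) outside grid")
    P = _slice_positions(flatmap, w)
    up, um = min(u0 + 1, nu - 1), max(u0 - 1, 0)
    vp, vm = min(v0 + 1, nv - 1), max(v0 - 1, 0)
    ru = (P[up, v0] - P[um, v0]) / (up - um)
    rv = (P[u0, vp] - P[u0, vm]) / (vp - vm)
    return float(ru @ ru), float(ru @ rv), float(rv @ rv)


def singular_values(E: float, F: float, G: float):
    """sigma_1 >= sigma_2: square roots of the eigenvalues of [[E, F], [F, G]].

    Closed form: sigma^2 = (E + G)/2 +- sqrt(((E - G)/2)^2 + F^2).
    """
    E = np.asarray(E, float)
    G = np.asarray(G, float)
    F = np.asarray(F, float)
    if np.any(E <= 0) or np.any(G <= 0) or np.any(E * G - F**2 <= 0):
        raise ValueError("degenerate mapping: first fundamental form not positive definite")
    half_tr = (E + G) / 2.0
    disc = np.sqrt(((E - G) / 2.0) ** 2 + F**2)
    s1 = np.sqrt(half_tr + disc)
    s2 = np.sqrt(np.maximum(half_tr - disc, 0.0))
    return s1, s2


def distortion_map(flatmap: FlatMap, w: float | None = None) -> DistortionMap:
    """Full-slice distortion maps at slice w (default: the central slice).

    Interior nodes use central differences of the slice positions; edge nodes
    fall back to one-sided differences and are flagged.
    """
    if w is None:
        w = flatmap.w_c
    P = _slice_positions(flatmap, float(w))
    ru = np.gradient(P, axis=0)   # central interior, one-sided at edges
    rv = np.gradient(P, axis=1)
    E = np.einsum("ijk,ijk->ij", ru, ru)
    F = np.einsum("ijk,ijk->ij", ru, rv)
    G = np.einsum("ijk,ijk->ij", rv, rv)
    half_tr = (E + G) / 2.0
    disc = np.sqrt(((E - G) / 2.0) ** 2 + F**2)
    s1 = np.sqrt(np.maximum(half_tr + disc, 0.0))
    s2 = np.sqrt(np.maximum(half_tr - disc, 0.0))
    prod = s1 * s2
    sign = np.where(prod >= 1.0, 1, -1).astype(np.int8)
    with np.errstate(divide="ignore", invalid="ignore"):
        area = np.where(prod >= 1.0, prod, np.where(prod > 0, 1.0 / prod, np.inf))
        shape = np.where(s2 > 0, s1 / s2, np.inf)
    edge = np.zeros(E.shape, dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    return DistortionMap(E=E, F=F, G=G, sigma1=s1, sigma2=s2,
                         area=area, area_sign=sign, shape=shape, edge=edge, w=float(w))


def optcuts_energy(sigma1, sigma2):
    """Symmetric Dirichlet distortion energy s1^2 + s2^2 + s1^-2 + s2^-2.

    Minimized (= 4) exactly at an isometry (sigma1 = sigma2 = 1); used as a
    diagnostic for externally computed mesh parameterizations.
    """
    s1 = np.asarray(sigma1, float)
    s2 = np.asarray(sigma2, float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("singular values must be positive")
    return s1**2 + s2**2 + s1**-2 + s2**-2


def write_distortion_maps(dm: DistortionMap, area_path, shape_path, sign_path=None,
                          voxel_size: float = 1.0) -> None:
    """Write area/shape maps as one-slice float MRC volumes (+ int8 sign map)."""
    write_volume(VoxelVolume(dm.area[:, :, None].astype(np.float32), voxel_size), area_path)
    write_volume(VoxelVolume(dm.shape[:, :, None].astype(np.float32), voxel_size), shape_path)
    if sign_path is not None:
        write_volume(VoxelVolume(dm.area_sign[:, :, None].astype(np.float32), voxel_size), sign_path)
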
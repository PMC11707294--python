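"""Cylindrical unrolling and flattened-tomogram generation.

The fitted membrane is projected onto a best-fit cylindrical surface (a
polynomial profile ``z = h(y)`` bent along one in-plane axis, or an elliptic
cylinder for closed membranes) and unrolled with equal arc-length sampling,
so the intermediate flattening step itself introduces no distortion.  The
result is a ``FlatMap``: an integer (u, v) grid of raw-space surface points
``S(u, v)`` and unit normals ``N(u, v)``.  Each flattened voxel (u, v, w)
maps to ``S(u, v) + (w - w_c) * N(u, v)`` in the raw tomogram; rendering is
trilinear interpolation at those locations.  The same machinery accepts an
externally UV-parameterized triangle mesh, whose three coordinate functions
X(u, v), Y(u, v), Z(u, v) are fitted by thin-plate splines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.transform import Rotation

from .surface_model import (
    FitParams,
    FrameTransform,
    HeightSurface,
    PolynomialSurface,
    TPSSurface,
    determine_frame,
    fit_polynomial,
    fit_tps,
)
from .volio import ParamMesh, PointSet, VoxelVolume

__all__ = [
    "CylinderModel",
    "FlatMap",
    "FlattenedTomogram",
    "fit_cylinder_poly",
    "fit_cylinder_elliptic",
    "arc_length",
    "arc_length_inverse",
    "build_flatmap",
    "render_flattened",
    "flat_to_raw",
    "raw_to_flat",
    "slice_to_mesh",
    "flatten_mesh",
    "flatten_volume",
]


class CylinderModel:
    """The intermediate cylindrical surface and its arc-length tables.

    ``poly_open``: profile z = h(y) = sum a_n y^n bent along the local y axis.
    ``elliptic_closed``: an elliptic cross-section in the plane perpendicular
    to the cylinder axis.  Both cache a strictly increasing arc-length map
    v(y) (v(y_min) = 0) and its inverse y(v) on a dense table.
    """

    def __init__(self, kind: str, coeffs=None, y_min: float = 0.0, y_max: float = 1.0,
                 center=None, semi_axes=None, angle: float = 0.0):
        self.kind = kind
        self.coeffs = None if coeffs is None else np.asarray(coeffs, float)
        self.y_min = float(y_min)
        self.y_max = float(y_max)
        self.center = None if center is None else np.asarray(center, float)
        self.semi_axes = None if semi_axes is None else np.asarray(semi_axes, float)
        self.angle = float(angle)
        if kind == "elliptic_closed" and (self.semi_axes is None or np.any(self.semi_axes <= 0)):
            raise ValueError("elliptic cylinder needs positive semi-axes")
        self._build_tables()

    # -- profile -----------------------------------------------------------
    def h(self, y):
        return np.polynomial.polynomial.polyval(y, self.coeffs)

    def h_prime(self, y):
        return np.polynomial.polynomial.polyval(y, np.polynomial.polynomial.polyder(self.coeffs))

    def _speed(self, y):
        if self.kind == "poly_open":
            return np.sqrt(1.0 + self.h_prime(y) ** 2)
        a, b = self.semi_axes
        # parameter y is the ellipse angle phi here
        return np.sqrt((a * np.sin(y)) ** 2 + (b * np.cos(y)) ** 2)

    def _build_tables(self) -> None:
        n = 4001
        ys = np.linspace(self.y_min, self.y_max, n)
        sp = self._speed(ys)
        # cumulative Simpson via fine trapezoid on a dense grid
        v = np.concatenate([[0.0], np.cumsum((sp[1:] + sp[:-1]) * 0.5 * np.diff(ys))])
        if np.any(np.diff(v) <= 0):
            raise ValueError("arc length v(y) is not strictly increasing")
        self._v_of_y = PchipInterpolator(ys, v)
        self._y_of_v = PchipInterpolator(v, ys)
        self.total_arc = float(v[-1])

    def arc_length(self, y):
        return self._v_of_y(y)

    def arc_length_inverse(self, v):
        return self._y_of_v(v)


def arc_length(cyl: CylinderModel, y):
    """v(y): arc length along the cylinder profile from y_min."""
    return cyl.arc_length(y)


def arc_length_inverse(cyl: CylinderModel, v):
    return cyl.arc_length_inverse(v)


# ---------------------------------------------------------------------------
# Cylinder fitting


def _bend_axis_angle(pts_local: np.ndarray) -> float:
    """In-plane angle of the direction of largest curvature of a quadratic
    pre-fit, used as the bend (local y) axis of the cylinder."""
    surf = fit_polynomial(PointSet(pts_local), 2)
    C = surf.coefficients
    H = np.array([[2 * C[2, 0], C[1, 1]], [C[1, 1], 2 * C[0, 2]]])
    evals, evecs = np.linalg.eigh(H)
    d = evecs[:, np.argmax(np.abs(evals))]
    return float(np.arctan2(d[1], d[0]))


def fit_cylinder_poly(points: PointSet, degree: int = 2,
                      frame: FrameTransform | None = None,
                      bend_angle: float | None = None,
                      max_nfev: int = 200) -> tuple[FrameTransform, CylinderModel]:
    """Jointly fit the frame rotation and the profile z = h(y).

    Starting from the plane-fit frame, the local frame is first rotated
    in-plane so the direction of largest curvature becomes the y axis, then
    a nonlinear least-squares solve over a rotation perturbation and the
    polynomial coefficients minimizes sum (z_i - h(y_i))^2.
    """
    pts = np.asarray(points.points, float)
    if frame is None:
        frame = determine_frame(points, method="plane_fit")
    local = frame.to_local(pts)
    ang = _bend_axis_angle(local) if bend_angle is None else bend_angle
    # rotate in-plane so the bend direction is local +y
    c, s = np.cos(ang - np.pi / 2), np.sin(ang - np.pi / 2)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    R0 = frame.R @ Rz
    t = frame.t

    local0 = (pts - t) @ R0
    coef0 = np.polynomial.polynomial.polyfit(local0[:, 1], local0[:, 2], degree)

    def unpack(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        return R0 @ rot, p[3:]

    def resid(p):
        R, coef = unpack(p)
        loc = (pts - t) @ R
        return loc[:, 2] - np.polynomial.polynomial.polyval(loc[:, 1], coef)

    p0 = np.concatenate([np.zeros(3), coef0])
    sol = least_squares(resid, p0, max_nfev=max_nfev)
    if not sol.success:
        warnings.warn("cylinder fit did not converge; returning best iterate", stacklevel=2)
    R, coef = unpack(sol.x)
    # re-impose the sign convention on the new frame
    if R[2, 2] < 0:
        flip = np.diag([1.0, -1.0, -1.0])  # keep x, flip y and z
        R = R @ flip
        # y -> -y, z -> -z turns z = h(y) into a_n -> (-1)^(n+1) a_n
        coef = coef * (-1.0) ** (1 + np.arange(degree + 1))
    final = FrameTransform(R=R, t=t)
    local = final.to_local(pts)
    cyl = CylinderModel("poly_open", coeffs=coef,
                        y_min=float(local[:, 1].min()), y_max=float(local[:, 1].max()))
    cyl.fit_residual = float(np.sqrt(np.mean(sol.fun**2)))
    return final, cyl


def _cross_section_open(proj: np.ndarray, n_bins: int = 12) -> bool:
    """True when the projected cross-section looks like an open curve.

    A closed ring is two-valued along its principal in-plane direction, so
    per-bin spread of the secondary coordinate stays comparable to the global
    spread; an open arc is (mostly) single-valued."""
    q = proj - proj.mean(axis=0)
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    a = q @ vt[0]
    b = q @ vt[1]
    rng_b = b.max() - b.min()
    if rng_b == 0:
        return True
    edges = np.linspace(a.min(), a.max(), n_bins + 1)
    spreads = []
    for k in range(n_bins):
        sel = (a >= edges[k]) & (a <= edges[k + 1])
        if sel.sum() >= 3:
            spreads.append(b[sel].max() - b[sel].min())
    return bool(np.median(spreads) < 0.5 * rng_b)


def fit_cylinder_elliptic(points: PointSet) -> tuple[FrameTransform, CylinderModel]:
    """Fit an elliptic cylinder to points that surround a closed cross-section.

    The cylinder axis is the largest-variance direction of the cloud; the
    projected points are fitted with a direct least-squares ellipse.  Warns
    (recommending the open polynomial cylinder) when the projected points
    cover less than 180 degrees around the center.
    """
    from skimage.measure import EllipseModel

    pts = np.asarray(points.points, float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)

    # The cylinder axis is the principal direction whose projection leaves the
    # thinnest elliptical ring; try all three and keep the best fit.
    best = None
    for k in range(3):
        cand = evecs[:, k]
        u = evecs[:, (k + 1) % 3]
        v = np.cross(cand, u)
        proj = np.column_stack([(pts - centroid) @ u, (pts - centroid) @ v])
        em = EllipseModel.from_estimate(proj)
        if not em:
            continue
        resid = float(np.sqrt(np.mean(em.residuals(proj) ** 2)))
        if best is None or resid < best[0]:
            best = (resid, cand, u, v, em, proj)
    if best is None:
        raise ValueError("ellipse fit failed")
    _, axis, e1, e2, em, proj = best
    if axis[0] < 0:
        axis = -axis
        e2 = -e2
        proj = np.column_stack([proj[:, 0], -proj[:, 1]])
        em = EllipseModel.from_estimate(proj)
    (xc, yc), (a, b), theta = em.center, em.axis_lengths, em.theta
    if a < b:
        a, b = b, a
        theta += np.pi / 2

    if _cross_section_open(proj):
        warnings.warn(
            "points cover less than 180 deg of the cross-section; "
            "consider the open polynomial cylinder instead", stacklevel=2)

    # frame: local x = cylinder axis; y/z span the cross-section plane
    ex = axis
    ey = np.cos(theta) * e1 + np.sin(theta) * e2   # ellipse major axis
    ez = np.cross(ex, ey)
    R = np.column_stack([ex, ey, ez])
    if np.linalg.det(R) < 0:
        ey = -ey
        R = np.column_stack([ex, ey, ez])
    t = centroid + e1 * xc + e2 * yc
    frame = FrameTransform(R=R, t=t)
    cyl = CylinderModel("elliptic_closed", center=np.zeros(2), semi_axes=(a, b),
                        y_min=0.0, y_max=2 * np.pi)
    return frame, cyl


# ---------------------------------------------------------------------------
# FlatMap


@dataclass
class FlatMap:
    """The (u, v) -> raw-space sample grid at the heart of all conversion.

    ``S[u, v]`` are raw coordinates of the membrane surface, ``N[u, v]`` unit
    normals.  The slab spans w in [0, 2 w_t]; the central slice index is
    ``w_c = w_t`` (0-based; documentation uses the 1-based w_t + 1).
    """

    S: np.ndarray                 # (nu, nv, 3)
    N: np.ndarray                 # (nu, nv, 3)
    w_t: int
    valid: np.ndarray | None = None   # (nu, nv) bool, True where S is defined
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, float)
        self.N = np.asarray(self.N, float)
        if self.valid is None:
            self.valid = np.ones(self.S.shape[:2], dtype=bool)
        self._tree = None

    @property
    def w_c(self) -> int:
        return self.w_t

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape[:2]

    def node_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.S[self.valid])
            iu, iv = np.nonzero(self.valid)
            self._node_index = np.column_stack([iu, iv])
        return self._tree


@dataclass
class FlattenedTomogram:
    volume: VoxelVolume
    flatmap: FlatMap
    valid: np.ndarray  # (nu, nv, nw) bool


def _grid_normals(S: np.ndarray) -> np.ndarray:
    """Unit normals from the sampled surface grid: cross product of the
    numerical tangents (central differences, one-sided at the edges)."""
    ru = np.gradient(S, axis=0)
    rv = np.gradient(S, axis=1)
    n = np.cross(ru, rv)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def build_flatmap(surface: HeightSurface, frame: FrameTransform, cyl: CylinderModel,
                  w_t: int = 15) -> FlatMap:
    """Sample the surface on the integer (u, v) grid (1 px spacing).

    u runs along local x; v is arc length along the cylinder profile, so
    integer v steps correspond to equal arc-length steps on the cylinder.
    S(u, v) = frame.to_raw(x, y(v), f(x, y(v))); N from the sampled grid.
    """
    x0, x1, y0, y1 = surface.domain
    if x1 <= x0 or y1 <= y0:
        raise ValueError("surface footprint is empty")
    if cyl.kind == "poly_open":
        v_max = float(cyl.arc_length(min(y1, cyl.y_max)))
        v_min = float(cyl.arc_length(max(y0, cyl.y_min)))
    else:
        v_min, v_max = 0.0, cyl.total_arc
    us = np.arange(np.ceil(x0), np.floor(x1) + 1.0)
    vs = np.arange(np.ceil(v_min), np.floor(v_max) + 1.0)
    if us.size == 0 or vs.size == 0:
        raise ValueError("surface footprint is empty")

    if cyl.kind == "poly_open":
        ys = np.asarray(cyl.arc_length_inverse(vs), float)
        U, Y = np.meshgrid(us, ys, indexing="ij")
        Z = surface.evaluate(U, Y)
        local = np.stack([U, Y, Z], axis=-1)
        S = local @ frame.R.T + frame.t
    else:
        # elliptic: (u, v) live on the cylinder surface; the height surface
        # f(u, v) is a radial offset from the ellipse along its outward normal
        a, b = cyl.semi_axes
        phis = np.asarray(cyl.arc_length_inverse(vs), float)
        U, PHI = np.meshgrid(us, phis, indexing="ij")
        F = surface.evaluate(U, np.broadcast_to(vs, U.shape))
        ey, ez = np.cos(PHI), np.sin(PHI)
        base_y, base_z = a * ey, b * ez
        ny, nz = b * ey, a * ez
        nn = np.sqrt(ny**2 + nz**2)
        ny, nz = ny / nn, nz / nn
        local = np.stack([U, base_y + F * ny, base_z + F * nz], axis=-1)
        S = local @ frame.R.T + frame.t

    N = _grid_normals(S)
    fm = FlatMap(S=S, N=N, w_t=int(w_t),
                 provenance={"u_offset": float(us[0]), "v_offset": float(vs[0]),
                             "kind": cyl.kind, "surface": getattr(surface, "kind", "?")})
    return fm


def render_flattened(tomo: VoxelVolume, flatmap: FlatMap,
                     fill: float | None = None) -> FlattenedTomogram:
    """Render the flattened tomogram: dims (n_u, n_v, 2 w_t + 1).

    Voxel (u, v, w) is a trilinear sample of the raw tomogram at
    S(u, v) + (w - w_c) N(u, v); out-of-bounds samples get the fill value
    (default: the raw tomogram mean) and a False validity flag.
    """
    wt = flatmap.w_t
    ws = np.arange(2 * wt + 1) - flatmap.w_c
    pos = flatmap.S[:, :, None, :] + ws[None, None, :, None] * flatmap.N[:, :, None, :]
    dims = np.array(tomo.data.shape, float)
    inside = np.all((pos >= 0) & (pos <= dims - 1), axis=-1)
    inside &= flatmap.valid[:, :, None]
    if fill is None:
        fill = float(tomo.data.mean())
    coords = pos.reshape(-1, 3).T
    vals = ndimage.map_coordinates(tomo.data.astype(float), coords, order=1,
                                   mode="constant", cval=fill)
    out = vals.reshape(pos.shape[:3])
    out[~inside] = fill
    vol = VoxelVolume(out.astype(np.float32), voxel_size=tomo.voxel_size)
    return FlattenedTomogram(volume=vol, flatmap=flatmap, valid=inside)


def _interp_SN(flatmap: FlatMap, u, v):
    """Bilinear interpolation of S and N at continuous (u, v); N re-normalized."""
    u = np.atleast_1d(np.asarray(u, float))
    v = np.atleast_1d(np.asarray(v, float))
    nu, nv = flatmap.shape
    if np.any(u < 0) or np.any(u > nu - 1) or np.any(v < 0) or np.any(v > nv - 1):
        raise ValueError("(u, v) outside the flatmap grid")
    coords = np.stack([u, v])
    S = np.stack([ndimage.map_coordinates(flatmap.S[..., d], coords, order=1)
                  for d in range(3)], axis=-1)
    N = np.stack([ndimage.map_coordinates(flatmap.N[..., d], coords, order=1)
                  for d in range(3)], axis=-1)
    N = N / np.linalg.norm(N, axis=-1, keepdims=True)
    return S, N


def flat_to_raw(flatmap: FlatMap, uvw) -> np.ndarray:
    """Map continuous flattened coordinates (u, v, w) to raw (X, Y, Z)."""
    uvw = np.atleast_2d(np.asarray(uvw, float))
    S, N = _interp_SN(flatmap, uvw[:, 0], uvw[:, 1])
    out = S + (uvw[:, 2] - flatmap.w_c)[:, None] * N
    return out if out.shape[0] > 1 else out[0]


def raw_to_flat(flatmap: FlatMap, xyz, tol: float = 0.5,
                max_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Invert the flattening map: raw (X, Y, Z) -> (u, v, w).

    Seeds (u, v) at the nearest grid node (spatial index), refines by
    Gauss-Newton on the squared distance to the interpolated surface, then
    w = w_c + (P - S) . N.  Returns (uvw, residual); points whose tangential
    residual exceeds ``tol`` or that lie beyond the slab are flagged with
    NaN coordinates.
    """
    P = np.atleast_2d(np.asarray(xyz, float))
    tree = flatmap.node_tree()
    _, idx = tree.query(P)
    nodes = flatmap._node_index[idx].astype(float)
    nu, nv = flatmap.shape
    out = np.full((len(P), 3), np.nan)
    resid = np.full(len(P), np.inf)
    for i, (p, (u, v)) in enumerate(zip(P, nodes)):
        uv = np.array([u, v])
        h = 0.5
        for _ in range(max_iter):
            uv[0] = np.clip(uv[0], 0, nu - 1)
            uv[1] = np.clip(uv[1], 0, nv - 1)
            S0, _ = _interp_SN(flatmap, uv[0], uv[1])
            # numerical Jacobian of S wrt (u, v)
            up, um = min(uv[0] + h, nu - 1), max(uv[0] - h, 0)
            vp, vm = min(uv[1] + h, nv - 1), max(uv[1] - h, 0)
            Su = (_interp_SN(flatmap, up, uv[1])[0] - _interp_SN(flatmap, um, uv[1])[0]) / (up - um)
            Sv = (_interp_SN(flatmap, uv[0], vp)[0] - _interp_SN(flatmap, uv[0], vm)[0]) / (vp - vm)
            J = np.stack([Su[0], Sv[0]], axis=1)      # (3, 2)
            r = (p - S0[0])
            JtJ = J.T @ J
            try:
                step = np.linalg.solve(JtJ, J.T @ r)
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -2.0, 2.0)
            uv = uv + step
            if np.linalg.norm(step) < 1e-8:
                break
        uv[0] = np.clip(uv[0], 0, nu - 1)
        uv[1] = np.clip(uv[1], 0, nv - 1)
        S0, N0 = _interp_SN(flatmap, uv[0], uv[1])
        d = p - S0[0]
        w_off = float(d @ N0[0])
        tangential = np.linalg.norm(d - w_off * N0[0])
        resid[i] = tangential
        if tangential <= tol and abs(w_off) <= flatmap.w_t + 0.5:
            out[i] = (uv[0], uv[1], flatmap.w_c + w_off)
    return (out if len(P) > 1 else out[0]), (resid if len(P) > 1 else resid[0])


def slice_to_mesh(flatmap: FlatMap, w: float | None = None) -> ParamMesh:
    """Triangulate a flattened-tomogram slice as a surface in raw space.

    Vertices are S + (w - w_c) N on the (u, v) grid, texture coordinates the
    (u, v) indices: the distortion-free reference view of that slice.
    """
    if w is None:
        w = flatmap.w_c
    if not (0 <= w <= 2 * flatmap.w_t):
        raise ValueError("w outside the slab")
    nu, nv = flatmap.shape
    V = (flatmap.S + (w - flatmap.w_c) * flatmap.N).reshape(-1, 3)
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    T = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            faces.append((a, a + nv, a + 1))
            faces.append((a + 1, a + nv, a + nv + 1))
    return ParamMesh(vertices=V, faces=np.array(faces, int), texcoords=T)


def flatten_mesh(tomo: VoxelVolume, mesh: ParamMesh, w_t: int = 15,
                 uv_scale: float = 1.0, smoothness: float = 0.0,
                 fill: float | None = None) -> tuple[FlatMap, FlattenedTomogram]:
    """Flatten a surface given as a UV-parameterized triangle mesh.

    The three coordinate functions X(u, v), Y(u, v), Z(u, v) are fitted by
    thin-plate splines over the (scaled) texture coordinates and sampled on
    the integer (u, v) grid inside the convex hull of the texcoords; normals
    and rendering then follow the standard pathway.  ``uv_scale`` converts
    normalized parameterizations to ~1 voxel of arc per uv unit.
    """
    mesh.validate()
    tc = mesh.texcoords * uv_scale
    # reject collapsed parameterizations: compare total uv area with 3D area
    v, f = mesh.vertices, mesh.faces
    a3 = 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1).sum()
    e1 = tc[f[:, 1]] - tc[f[:, 0]]
    e2 = tc[f[:, 2]] - tc[f[:, 0]]
    a2 = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]).sum()
    if a2 < 0.01 * a3:
        raise ValueError(
            f"collapsed parameterization: uv area {a2:.3g} << 3D area {a3:.3g}; "
            "the distortion would be extreme")

    # subsample very dense meshes for the TPS solve
    pts2 = tc
    vals = mesh.vertices
    if len(pts2) > 3000:
        sel = np.random.default_rng(0).choice(len(pts2), 3000, replace=False)
        pts2, vals = pts2[sel], vals[sel]
    fits = [TPSSurface.solve(pts2, vals[:, d], smoothness) for d in range(3)]

    us = np.arange(np.ceil(tc[:, 0].min()), np.floor(tc[:, 0].max()) + 1.0)
    vs = np.arange(np.ceil(tc[:, 1].min()), np.floor(tc[:, 1].max()) + 1.0)
    if us.size == 0 or vs.size == 0:
        raise ValueError("surface footprint is empty")
    U, V = np.meshgrid(us, vs, indexing="ij")
    S = np.stack([fits[d].evaluate(U, V) for d in range(3)], axis=-1)
    hull = Delaunay(tc)
    inside = hull.find_simplex(np.column_stack([U.ravel(), V.ravel()])) >= 0
    valid = inside.reshape(U.shape)
    N = _grid_normals(S)
    fm = FlatMap(S=S, N=N, w_t=int(w_t), valid=valid,
                 provenance={"u_offset": float(us[0]), "v_offset": float(vs[0]),
                             "kind": "mesh", "uv_scale": uv_scale})
    return fm, render_flattened(tomo, fm, fill=fill)


# ---------------------------------------------------------------------------
# High-level pipeline


def flatten_volume(tomo: VoxelVolume, points: PointSet, mode: str = "poly",
                   surface_kind: str = "tps", poly_degree: int = 8,
                   cyl_degree: int = 2, w_t: int = 15,
                   fit_params: FitParams | None = None,
                   fill: float | None = None):
    """One-call pipeline: frame + surface + cylinder fit, flatmap, rendering.

    ``mode``: 'plane' projects along the local z axis (u = x, v = y);
    'poly' unrolls over a best-fit polynomial cylinder; 'elliptic' over an
    elliptic cylinder.  Returns (FlatMap, FlattenedTomogram, fit objects).
    """
    fit_params = fit_params or FitParams()
    if mode == "plane":
        frame = determine_frame(points, method="plane_fit")
        local = PointSet(frame.to_local(points.points))
        surface = (fit_tps(local, fit_params) if surface_kind == "tps"
                   else fit_polynomial(local, poly_degree))
        y0, y1 = local.points[:, 1].min(), local.points[:, 1].max()
        cyl = CylinderModel("poly_open", coeffs=[0.0], y_min=y0, y_max=y1)
        if surface.domain is None:
            surface.domain = (local.points[:, 0].min(), local.points[:, 0].max(), y0, y1)
    elif mode == "poly":
        frame, cyl = fit_cylinder_poly(points, degree=cyl_degree)
        local = PointSet(frame.to_local(points.points))
        surface = (fit_tps(local, fit_params) if surface_kind == "tps"
                   else fit_polynomial(local, poly_degree))
        if surface.domain is None:
            surface.domain = (local.points[:, 0].min(), local.points[:, 0].max(),
                              local.points[:, 1].min(), local.points[:, 1].max())
    elif mode == "elliptic":
        frame, cyl = fit_cylinder_elliptic(points)
        local = frame.to_local(points.points)
        a, b = cyl.semi_axes
        phi = np.arctan2(local[:, 2] / b, local[:, 1] / a)
        varc = np.asarray(cyl.arc_length(np.mod(phi, 2 * np.pi)), float)
        ny = b * np.cos(phi)
        nz = a * np.sin(phi)
        nn = np.sqrt(ny**2 + nz**2)
        radial = ((local[:, 1] - a * np.cos(phi)) * ny + (local[:, 2] - b * np.sin(phi)) * nz) / nn
        cyl_pts = PointSet(np.column_stack([local[:, 0], varc, radial]))
        surface = (fit_tps(cyl_pts, fit_params) if surface_kind == "tps"
                   else fit_polynomial(cyl_pts, poly_degree))
        if surface.domain is None:
            surface.domain = (local[:, 0].min(), local[:, 0].max(), 0.0, cyl.total_arc)
    else:
        raise ValueError(f"unknown flattening mode {mode!r}")

    if surface.kind == "polynomial" and surface.domain is None:
        surface.domain = (local.points[:, 0].min(), local.points[:, 0].max(),
                          local.points[:, 1].min(), local.points[:, 1].max())
    fm = build_flatmap(surface, frame, cyl, w_t=w_t)
    flat = render_flattened(tomo, fm, fill=fill)
    return fm, flat, {"frame": frame, "surface": surface, "cylinder": cyl}
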
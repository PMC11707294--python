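"""Local frame determination and height-surface fitting.

The membrane is described as a single-valued height field ``z = f(x, y)`` in
a local Cartesian frame chosen so that the surface looks flat from the local
z direction.  Two fit families are provided: a bivariate polynomial of user
degree, and a thin-plate spline (TPS) over grid-downsampled control points
with optional smoothing and a one-shot outlier refit.  Both expose analytic
evaluation and gradients, from which unit surface normals follow as the
normalized ``(-f_x, -f_y, 1)`` rotated into raw coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .volio import PointSet

__all__ = [
    "FrameTransform",
    "HeightSurface",
    "PolynomialSurface",
    "TPSSurface",
    "FitParams",
    "determine_frame",
    "fit_polynomial",
    "fit_tps",
    "evaluate",
    "gradient",
    "normal_raw",
]


@dataclass
class FrameTransform:
    """Rigid map from local (x, y, z) to raw (X, Y, Z): ``P_raw = R p + t``."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-9:
            raise ValueError("R is not a proper rotation (det != +1)")

    def to_raw(self, pts_local: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts_local) @ self.R.T + self.t

    def to_local(self, pts_raw: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts_raw) - self.t) @ self.R


@dataclass
class FitParams:
    downsample_spacing: float = 12.0
    smoothness: float = 0.0
    refit_outlier_mult: float = 3.0

    def __post_init__(self) -> None:
        if self.downsample_spacing < 1:
            raise ValueError("downsample_spacing must be >= 1")
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")


class HeightSurface:
    """Base class for differentiable height fields z = f(x, y)."""

    kind: str = "abstract"
    domain: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)  # x0, x1, y0, y1

    def evaluate(self, x, y):
        raise NotImplementedError

    def gradient(self, x, y):
        raise NotImplementedError

    def __call__(self, x, y):
        return self.evaluate(x, y)


class PolynomialSurface(HeightSurface):
    """Bivariate polynomial f(x,y) = sum_{m+n<=N} a_mn x^m y^n.

    Fitting is done on centered/scaled coordinates for conditioning; the
    ``coefficients`` property converts back to raw-monomial a_mn.
    """

    kind = "polynomial"

    def __init__(self, degree: int, coeffs_scaled: np.ndarray,
                 center: np.ndarray, scale: np.ndarray,
                 domain=None, residuals: np.ndarray | None = None):
        self.degree = int(degree)
        self._c = np.asarray(coeffs_scaled, dtype=float)   # packed by (m, n)
        self._center = np.asarray(center, dtype=float)
        self._scale = np.asarray(scale, dtype=float)
        self.domain = domain
        self.residuals = residuals
        self._exps = _poly_exponents(self.degree)

    @property
    def coefficients(self) -> np.ndarray:
        """Dense (N+1, N+1) array C with f = sum C[m, n] x^m y^n (raw coords)."""
        N = self.degree
        C = np.zeros((N + 1, N + 1))
        cx, cy = self._center
        sx, sy = self._scale
        for (m, n), a in zip(self._exps, self._c):
            px = npoly.polypow([-cx / sx, 1.0 / sx], m) if m else np.array([1.0])
            py = npoly.polypow([-cy / sy, 1.0 / sy], n) if n else np.array([1.0])
            C[: len(px), : len(py)] += a * np.outer(px, py)
        return C

    def coefficient(self, m: int, n: int) -> float:
        return float(self.coefficients[m, n])

    def _uv(self, x, y):
        return ((np.asarray(x, float) - self._center[0]) / self._scale[0],
                (np.asarray(y, float) - self._center[1]) / self._scale[1])

    def evaluate(self, x, y):
        xs, ys = self._uv(x, y)
        out = np.zeros(np.broadcast(xs, ys).shape)
        for (m, n), a in zip(self._exps, self._c):
            out = out + a * xs**m * ys**n
        return out if out.shape else float(out)

    def gradient(self, x, y):
        xs, ys = self._uv(x, y)
        shape = np.broadcast(xs, ys).shape
        gx = np.zeros(shape)
        gy = np.zeros(shape)
        for (m, n), a in zip(self._exps, self._c):
            if m:
                gx = gx + a * m * xs ** (m - 1) * ys**n
            if n:
                gy = gy + a * n * xs**m * ys ** (n - 1)
        gx = gx / self._scale[0]
        gy = gy / self._scale[1]
        if shape:
            return gx, gy
        return float(gx), float(gy)


def _poly_exponents(N: int) -> list[tuple[int, int]]:
    return [(m, n) for m in range(N + 1) for n in range(N + 1 - m) ]


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # phi(r) = r^2 log r = 0.5 r^2 log r^2; zero at r = 0 by continuity
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


class TPSSurface(HeightSurface):
    """Thin-plate spline z = sum w_i phi(|p - p_i|) + c0 + c1 x + c2 y.

    Smoothing enters as diagonal regularization of the kernel block, so
    ``smoothness = 0`` interpolates the control points exactly.
    """

    kind = "tps"

    def __init__(self, control_xy: np.ndarray, weights: np.ndarray,
                 affine: np.ndarray, smoothness: float, domain=None,
                 residuals: np.ndarray | None = None):
        self.control_xy = np.asarray(control_xy, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self.affine = np.asarray(affine, dtype=float)  # (c0, c1, c2)
        self.smoothness = float(smoothness)
        self.domain = domain
        self.residuals = residuals

    @classmethod
    def solve(cls, xy: np.ndarray, z: np.ndarray, smoothness: float) -> "TPSSurface":
        xy = np.asarray(xy, float)
        z = np.asarray(z, float)
        n = len(xy)
        if n < 4:
            raise ValueError(f"TPS needs >= 4 control points, got {n}")
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        K = _tps_kernel(d2) + smoothness * np.eye(n)
        P = np.column_stack([np.ones(n), xy])
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.concatenate([z, np.zeros(3)])
        sol = np.linalg.solve(A, b)
        surf = cls(xy, sol[:n], sol[n:], smoothness,
                   domain=(xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max()))
        surf.residuals = surf.evaluate(xy[:, 0], xy[:, 1]) - z
        return surf

    def evaluate(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        shape = np.broadcast(x, y).shape
        q = np.stack(np.broadcast_arrays(x, y), axis=-1).reshape(-1, 2)
        d2 = ((q[:, None, :] - self.control_xy[None, :, :]) ** 2).sum(-1)
        val = _tps_kernel(d2) @ self.weights + self.affine[0] \
            + self.affine[1] * q[:, 0] + self.affine[2] * q[:, 1]
        return val.reshape(shape) if shape else float(val[0])

    def gradient(self, x, y):
        # d/dx [0.5 r^2 log r^2] = (x - xi) * (log r^2 + 1)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        shape = np.broadcast(x, y).shape
        q = np.stack(np.broadcast_arrays(x, y), axis=-1).reshape(-1, 2)
        diff = q[:, None, :] - self.control_xy[None, :, :]
        r2 = (diff**2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fac = np.log(r2) + 1.0
        fac = np.where(r2 > 0, fac, 0.0)
        gx = (diff[..., 0] * fac) @ self.weights + self.affine[1]
        gy = (diff[..., 1] * fac) @ self.weights + self.affine[2]
        if shape:
            return gx.reshape(shape), gy.reshape(shape)
        return float(gx[0]), float(gy[0])


# ---------------------------------------------------------------------------


def determine_frame(points: PointSet, method: str = "plane_fit") -> FrameTransform:
    """Choose the local frame whose z-axis is the flattest viewing direction.

    ``plane_fit``: total-least-squares plane through the points (SVD); the
    plane normal becomes the local z-axis.  ``max_area``: the direction that
    maximizes the projected area of the point cloud, implemented as the
    smallest-eigenvalue direction of the point covariance.  The z sign is
    chosen to have a non-negative dot product with raw +Z (tie: +X), and the
    translation is the centroid rounded to the nearest integer voxel (so
    axis-aligned membranes stay grid-aligned).
    """
    pts = np.asarray(points.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points to determine a frame")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if method == "plane_fit":
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError("points are collinear; frame undetermined")
        zax = vt[2]
    elif method == "max_area":
        cov = np.cov(centered.T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[1] < 1e-12 * max(evals[2], 1.0):
            raise ValueError("points are collinear; frame undetermined")
        zax = evecs[:, 0]
    else:
        raise ValueError(f"unknown frame method {method!r}")
    if zax[2] < 0 or (zax[2] == 0 and zax[0] < 0):
        zax = -zax
    ref = np.array([1.0, 0.0, 0.0])
    if abs(zax @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    xax = ref - (ref @ zax) * zax
    xax /= np.linalg.norm(xax)
    yax = np.cross(zax, xax)
    R = np.column_stack([xax, yax, zax])
    return FrameTransform(R=R, t=np.round(centroid))


def fit_polynomial(points_local: PointSet, N: int) -> PolynomialSurface:
    """Least-squares bivariate polynomial fit of degree N to local points."""
    pts = np.asarray(points_local.points, dtype=float)
    exps = _poly_exponents(N)
    if len(pts) < len(exps):
        raise ValueError(f"need >= {len(exps)} points for degree {N}, got {len(pts)}")
    x, y, z = pts.T
    center = np.array([x.mean(), y.mean()])
    scale = np.array([max(np.abs(x - center[0]).max(), 1.0),
                      max(np.abs(y - center[1]).max(), 1.0)])
    xs, ys = (x - center[0]) / scale[0], (y - center[1]) / scale[1]
    A = np.column_stack([xs**m * ys**n for (m, n) in exps])
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < len(exps):
        raise ValueError(
            f"rank-deficient polynomial design (rank {rank} < {len(exps)}); try a lower degree"
        )
    surf = PolynomialSurface(N, coef, center, scale,
                             domain=(x.min(), x.max(), y.min(), y.max()))
    surf.residuals = A @ coef - z
    return surf


def _grid_downsample(pts: np.ndarray, spacing: float) -> np.ndarray:
    """One representative (the centroid) per spacing-sized (x, y) cell."""
    cells = np.floor(pts[:, :2] / spacing).astype(int)
    _, inv = np.unique(cells, axis=0, return_inverse=True)
    k = inv.max() + 1
    sums = np.zeros((k, 3))
    counts = np.bincount(inv, minlength=k).astype(float)
    for d in range(3):
        sums[:, d] = np.bincount(inv, weights=pts[:, d], minlength=k)
    return sums / counts[:, None]


def fit_tps(points_local: PointSet, params: FitParams | None = None) -> TPSSurface:
    """Grid-downsample local points, fit a smoothing TPS, refit once without
    large-residual control points."""
    params = params or FitParams()
    pts = np.asarray(points_local.points, dtype=float)
    ctrl = _grid_downsample(pts, params.downsample_spacing)
    if len(ctrl) < 4:
        raise ValueError(f"only {len(ctrl)} control points after downsampling; need >= 4")
    surf = TPSSurface.solve(ctrl[:, :2], ctrl[:, 2], params.smoothness)
    res = np.abs(surf.residuals)
    sd = res.std()
    if sd > 0:
        keep = res <= params.refit_outlier_mult * sd
        if keep.sum() >= 4 and not keep.all():
            surf = TPSSurface.solve(ctrl[keep, :2], ctrl[keep, 2], params.smoothness)
    return surf


def evaluate(surface: HeightSurface, x, y):
    return surface.evaluate(x, y)


def gradient(surface: HeightSurface, x, y):
    return surface.gradient(x, y)


def normal_raw(surface: HeightSurface, frame: FrameTransform, x, y) -> np.ndarray:
    """Unit surface normal in raw coordinates: R @ normalize(-f_x, -f_y, 1)."""
    gx, gy = surface.gradient(x, y)
    gx = np.asarray(gx, float)
    gy = np.asarray(gy, float)
    n_local = np.stack(np.broadcast_arrays(-gx, -gy, np.ones_like(gx)), axis=-1)
    n_local = n_local / np.linalg.norm(n_local, axis=-1, keepdims=True)
    return n_local @ frame.R.T
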
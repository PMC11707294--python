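"""Synthetic tomogram phantoms with analytic membranes and oriented particles.

Generates everything the pipeline consumes without external data: a density
volume containing a bilayer membrane (two parallel Gaussian-dark sheets, the
cryoET negative-contrast convention) on an analytic surface, a binary
membrane mask, exact ground-truth surface points and particle tables, and
optionally an analytically UV-parameterized triangle mesh.  Optional white
noise and a Fourier-space missing-wedge filter emulate the two dominant
artifacts of real tomograms.

Particle blobs are an elongated dark Gaussian plus a smaller satellite blob
displaced along the in-plane direction, so the in-plane angle psi* is
recoverable over the full 360 degrees.  psi* is measured in the
``projection_basis`` frame of the local membrane normal, matching the
convention used for projections and 2D-classification import.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .particles import projection_basis
from .volio import ParamMesh, PointSet, VoxelVolume

__all__ = ["PhantomSpec", "make_phantom", "make_wedge_filter", "apply_wedge"]

_SHAPES = ("plane", "poly_sheet", "circular_cylinder", "elliptic_cylinder",
           "sphere", "sinusoid_sheet")


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic tomogram.

    Geometry defaults give a gently curved membrane in a ~200 px box; the
    bilayer leaflet separation of 5 voxels and leaflet width ~1.2 voxels
    mimic a biological membrane at ~2 nm/voxel.
    """

    shape: str = "plane"
    dims: tuple[int, int, int] = (96, 96, 64)
    voxel_size: float = 1.0
    seed: int = 0
    # geometry
    z0: float | None = None                 # plane/sheet base height
    radius: float = 50.0                    # cylinder/sphere
    semi_axes: tuple[float, float] = (60.0, 40.0)
    center: tuple[float, float, float] | None = None
    amplitude: float = 5.0                  # sinusoid amplitude
    period: float = 60.0                    # sinusoid period
    coeffs: tuple[float, ...] = (0.0, 0.0, 0.01)   # poly_sheet z = sum c_n y^n
    angle_limit_deg: float = 60.0           # patch half-angle for cylinder/sphere
    # membrane profile
    bilayer_separation: float = 5.0
    leaflet_width: float = 1.2
    membrane_amp: float = 1.0
    mask_halfwidth: float | None = None     # default: separation/2 + leaflet width
    # particles
    n_particles: int = 0
    particle_offset: float = 6.0            # along +normal, extramembrane
    particle_amp: float = 1.5
    blob_sigmas: tuple[float, float, float] = (4.0, 2.0, 2.0)  # long, short, normal
    satellite_offset: float = 5.0
    satellite_amp: float = 1.0
    satellite_sigma: float = 1.6
    min_separation: float = 14.0
    margin: float = 12.0                    # keep particles away from volume faces
    placement: str = "random"               # or "grid": jittered grid, guaranteed separation
    # corruption
    noise_sigma: float = 0.0
    wedge_tilt_deg: float | None = None     # e.g. 60 -> +-60 degree tilt range
    make_mesh: bool = False
    mesh_spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; use one of {_SHAPES}")
        if self.seed is None:
            raise ValueError("seed is mandatory (all randomness must be reproducible)")


# ---------------------------------------------------------------------------
# Analytic geometry per shape


class _Geometry:
    """Signed distance to the membrane mid-surface and the outward normal."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        nx, ny, nz = spec.dims
        self.c = np.array(spec.center) if spec.center is not None else \
            np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
        if spec.shape in ("circular_cylinder", "elliptic_cylinder", "sphere"):
            # keep the shell inside the box by default: center low in z for patches
            pass
        self.z0 = spec.z0 if spec.z0 is not None else (nz - 1) / 2.0

    def height(self, X, Y):
        """Surface height Z = f(X, Y) for height-field shapes."""
        s = self.spec
        if s.shape == "plane":
            return np.full_like(np.asarray(X, float), self.z0)
        if s.shape == "sinusoid_sheet":
            return self.z0 + s.amplitude * np.sin(2 * np.pi * np.asarray(X, float) / s.period)
        if s.shape == "poly_sheet":
            return self.z0 + np.polynomial.polynomial.polyval(
                np.asarray(Y, float) - self.c[1], np.asarray(s.coeffs))
        raise ValueError(f"{s.shape} is not a height field")

    def signed_distance_and_normal(self, X, Y, Z):
        s = self.spec
        if s.shape in ("plane", "sinusoid_sheet", "poly_sheet"):
            f = self.height(X, Y)
            h = 1e-4
            fx = (self.height(X + h, Y) - self.height(X - h, Y)) / (2 * h)
            fy = (self.height(X, Y + h) - self.height(X, Y - h)) / (2 * h)
            norm = np.sqrt(1 + fx**2 + fy**2)
            d = (Z - f) / norm
            n = np.stack([-fx / norm, -fy / norm, 1.0 / norm], axis=-1)
            return d, n
        if s.shape == "circular_cylinder":
            dy, dz = Y - self.c[1], Z - self.c[2]
            rho = np.sqrt(dy**2 + dz**2)
            rho_safe = np.where(rho == 0, 1.0, rho)
            d = rho - s.radius
            n = np.stack([np.zeros_like(dy), dy / rho_safe, dz / rho_safe], axis=-1)
            return d, n
        if s.shape == "elliptic_cylinder":
            a, b = s.semi_axes
            dy, dz = Y - self.c[1], Z - self.c[2]
            phi = np.arctan2(dz / b, dy / a)
            by, bz = a * np.cos(phi), b * np.sin(phi)
            ny, nz = b * np.cos(phi), a * np.sin(phi)
            nn = np.sqrt(ny**2 + nz**2)
            ny, nz = ny / nn, nz / nn
            d = (dy - by) * ny + (dz - bz) * nz
            n = np.stack([np.zeros_like(dy), ny, nz], axis=-1)
            return d, n
        if s.shape == "sphere":
            dx, dy, dz = X - self.c[0], Y - self.c[1], Z - self.c[2]
            r = np.sqrt(dx**2 + dy**2 + dz**2)
            r_safe = np.where(r == 0, 1.0, r)
            d = r - s.radius
            n = np.stack([dx / r_safe, dy / r_safe, dz / r_safe], axis=-1)
            return d, n
        raise AssertionError(s.shape)

    def patch_weight(self, X, Y, Z):
        """1 inside the modeled membrane patch, 0 outside (cylinder/sphere caps)."""
        s = self.spec
        if s.shape in ("circular_cylinder", "sphere"):
            if s.angle_limit_deg >= 180:
                return np.ones_like(np.asarray(X, float))
            _, n = self.signed_distance_and_normal(X, Y, Z)
            cosang = n[..., 2]
            return (cosang >= np.cos(np.radians(s.angle_limit_deg))).astype(float)
        return np.ones_like(np.asarray(X, float))

    def sample_surface(self, spacing: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        """Exact points and normals on the mid-surface (the ground truth)."""
        s = self.spec
        nx, ny, nz = s.dims
        if s.shape in ("plane", "sinusoid_sheet", "poly_sheet"):
            xs = np.arange(2.0, nx - 2.0, spacing)
            ys = np.arange(2.0, ny - 2.0, spacing)
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            Z = self.height(X, Y)
            pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
        elif s.shape in ("circular_cylinder", "elliptic_cylinder"):
            lim = np.radians(s.angle_limit_deg if s.shape == "circular_cylinder" else 180.0)
            xs = np.arange(2.0, nx - 2.0, spacing)
            if s.shape == "circular_cylinder":
                dth = spacing / s.radius
                ths = np.arange(np.pi / 2 - lim, np.pi / 2 + lim + dth / 2, dth)
                X, TH = np.meshgrid(xs, ths, indexing="ij")
                Y = self.c[1] + s.radius * np.cos(TH)
                Z = self.c[2] + s.radius * np.sin(TH)
            else:
                a, b = s.semi_axes
                dth = spacing / max(a, b)
                ths = np.arange(0, 2 * np.pi, dth)
                X, TH = np.meshgrid(xs, ths, indexing="ij")
                Y = self.c[1] + a * np.cos(TH)
                Z = self.c[2] + b * np.sin(TH)
            pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
        elif s.shape == "sphere":
            lim = np.radians(s.angle_limit_deg)
            dphi = spacing / s.radius
            phis = np.arange(0.0, lim + dphi / 2, dphi)   # polar angle from +Z
            rows = []
            for phi in phis:
                rim = s.radius * np.sin(phi)
                nlam = max(int(np.ceil(2 * np.pi * rim / spacing)), 1)
                lams = np.arange(nlam) * 2 * np.pi / nlam
                rows.append(np.column_stack([
                    self.c[0] + rim * np.cos(lams),
                    self.c[1] + rim * np.sin(lams),
                    np.full(nlam, self.c[2] + s.radius * np.cos(phi)),
                ]))
            pts = np.vstack(rows)
        inb = np.all((pts >= 1.0) & (pts <= np.array(s.dims, float) - 2.0), axis=1)
        pts = pts[inb]
        _, n = self.signed_distance_and_normal(pts[:, 0], pts[:, 1], pts[:, 2])
        return pts, n

    def random_surface_points(self, rng, count: int) -> tuple[np.ndarray, np.ndarray]:
        """Random points + normals on the patch interior (for particles)."""
        s = self.spec
        nx, ny, nz = s.dims
        m = s.margin
        pts = []
        while len(pts) < count:
            if s.shape in ("plane", "sinusoid_sheet", "poly_sheet"):
                x = rng.uniform(m, nx - 1 - m)
                y = rng.uniform(m, ny - 1 - m)
                p = np.array([x, y, float(self.height(x, y))])
            elif s.shape == "circular_cylinder":
                lim = np.radians(s.angle_limit_deg) * 0.85
                x = rng.uniform(m, nx - 1 - m)
                th = np.pi / 2 + rng.uniform(-lim, lim)
                p = np.array([x, self.c[1] + s.radius * np.cos(th),
                              self.c[2] + s.radius * np.sin(th)])
            elif s.shape == "elliptic_cylinder":
                a, b = s.semi_axes
                x = rng.uniform(m, nx - 1 - m)
                th = rng.uniform(0, 2 * np.pi)
                p = np.array([x, self.c[1] + a * np.cos(th), self.c[2] + b * np.sin(th)])
            else:  # sphere
                lim = np.radians(s.angle_limit_deg) * 0.85
                phi = np.arccos(rng.uniform(np.cos(lim), 1.0))
                lam = rng.uniform(0, 2 * np.pi)
                p = self.c + s.radius * np.array([
                    np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), np.cos(phi)])
            if np.all(p >= m / 2) and np.all(p <= np.array(s.dims) - 1 - m / 2):
                pts.append(p)
        pts = np.array(pts)
        _, n = self.signed_distance_and_normal(pts[:, 0], pts[:, 1], pts[:, 2])
        return pts, n

    def grid_surface_points(self, rng, count: int, min_sep: float
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Jittered-grid placement on the patch: guaranteed pairwise separation.

        The surface is covered by a square grid in an (approximately)
        arc-length parameterization; each particle sits at a jittered cell
        center, so distances stay >= cell - 2*jitter >= min_sep.
        """
        s = self.spec
        nx = s.dims[0]
        m = s.margin
        if s.shape in ("plane", "sinusoid_sheet", "poly_sheet"):
            dom = ((m, nx - 1 - m), (m, s.dims[1] - 1 - m))
            to_surface = lambda a, b: np.array([a, b, float(self.height(a, b))])
        elif s.shape == "circular_cylinder":
            lim = np.radians(s.angle_limit_deg) * 0.85
            dom = ((m, nx - 1 - m), (-lim * s.radius, lim * s.radius))
            to_surface = lambda a, b: np.array([
                a, self.c[1] + s.radius * np.cos(np.pi / 2 + b / s.radius),
                self.c[2] + s.radius * np.sin(np.pi / 2 + b / s.radius)])
        else:
            raise ValueError(f"grid placement not supported for shape {s.shape!r}")
        La = dom[0][1] - dom[0][0]
        Lb = dom[1][1] - dom[1][0]
        cell = np.sqrt(La * Lb / count)
        na, nb = int(La // cell), int(Lb // cell)
        while na * nb < count:
            cell *= 0.97
            na, nb = int(La // cell), int(Lb // cell)
        jitter = (cell - min_sep) / 2.0
        if jitter < 0:
            raise RuntimeError("could not place particles with the requested separation")
        jitter = min(jitter, cell / 4.0)
        ca = dom[0][0] + (La - na * cell) / 2 + cell * (0.5 + np.arange(na))
        cb = dom[1][0] + (Lb - nb * cell) / 2 + cell * (0.5 + np.arange(nb))
        cells = [(a, b) for a in ca for b in cb]
        sel = rng.permutation(len(cells))[:count]
        pts = []
        for k in sel:
            a, b = cells[k]
            pts.append(to_surface(a + rng.uniform(-jitter, jitter),
                                  b + rng.uniform(-jitter, jitter)))
        pts = np.array(pts)
        _, n = self.signed_distance_and_normal(pts[:, 0], pts[:, 1], pts[:, 2])
        return pts, n

    def make_mesh(self) -> ParamMesh | None:
        """Analytic UV-parameterized mesh (cylinder: (x, r*theta); sphere:
        equirectangular (R*longitude, R*polar))."""
        s = self.spec
        nx = s.dims[0]
        sp = s.mesh_spacing
        if s.shape == "circular_cylinder":
            lim = np.radians(s.angle_limit_deg)
            xs = np.arange(2.0, nx - 2.0, sp)
            dth = sp / s.radius
            ths = np.arange(np.pi / 2 - lim, np.pi / 2 + lim + dth / 2, dth)
            X, TH = np.meshgrid(xs, ths, indexing="ij")
            V = np.stack([X, self.c[1] + s.radius * np.cos(TH),
                          self.c[2] + s.radius * np.sin(TH)], -1).reshape(-1, 3)
            T = np.stack([X - xs[0], s.radius * (TH - ths[0])], -1).reshape(-1, 2)
            nu, nv = len(xs), len(ths)
        elif s.shape == "sphere":
            lim = np.radians(s.angle_limit_deg)
            dphi = sp / s.radius
            phis = np.arange(dphi, lim + dphi / 2, dphi)
            lams = np.arange(0, 2 * np.pi, dphi)
            PHI, LAM = np.meshgrid(phis, lams, indexing="ij")
            V = np.stack([
                self.c[0] + s.radius * np.sin(PHI) * np.cos(LAM),
                self.c[1] + s.radius * np.sin(PHI) * np.sin(LAM),
                self.c[2] + s.radius * np.cos(PHI)], -1).reshape(-1, 3)
            T = np.stack([s.radius * LAM, s.radius * PHI], -1).reshape(-1, 2)
            nu, nv = len(phis), len(lams)
        else:
            return None
        faces = []
        for i in range(nu - 1):
            for j in range(nv - 1):
                a = i * nv + j
                faces.append((a, a + nv, a + 1))
                faces.append((a + 1, a + nv, a + nv + 1))
        return ParamMesh(vertices=V, faces=np.array(faces, int), texcoords=T)


# ---------------------------------------------------------------------------


def make_wedge_filter(dims, tilt_range_deg: float) -> np.ndarray:
    """Binary missing-wedge mask in unshifted FFT ordering (1 = measured).

    With tilt axis +Y and tilt range +-T, a frequency is unmeasured when its
    direction in the (qx, qz) plane lies within (90 - T) degrees of the qz
    axis.  +-90 degrees passes everything.
    """
    if tilt_range_deg >= 90:
        return np.ones(dims)
    qx = np.fft.fftfreq(dims[0])[:, None, None]
    qz = np.fft.fftfreq(dims[2])[None, None, :]
    ang = np.arctan2(np.abs(qx), np.abs(qz))
    missing = ang < np.radians(90.0 - tilt_range_deg)
    mask = np.where(missing, 0.0, 1.0) * np.ones((1, dims[1], 1))
    mask[0, :, 0] = 1.0  # DC always measured
    return mask


def apply_wedge(data: np.ndarray, tilt_range_deg: float) -> np.ndarray:
    """Apply the missing-wedge filter to a real volume (Fourier masking)."""
    mask = make_wedge_filter(data.shape, tilt_range_deg)
    return np.real(np.fft.ifftn(np.fft.fftn(data) * mask))


def _add_blob(data: np.ndarray, center: np.ndarray, axes: np.ndarray,
              sigmas: np.ndarray, amp: float) -> None:
    """Subtract an anisotropic Gaussian blob (dark) in a local window."""
    r = int(np.ceil(3.5 * sigmas.max()))
    lo = np.maximum(np.floor(center).astype(int) - r, 0)
    hi = np.minimum(np.floor(center).astype(int) + r + 1, data.shape)
    if np.any(lo >= hi):
        return
    xs = [np.arange(lo[d], hi[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    d = np.stack([X - center[0], Y - center[1], Z - center[2]], -1)
    q = np.einsum("...k,jk->...j", d, axes)  # components along blob axes
    arg = (q / sigmas) ** 2
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] -= amp * np.exp(-0.5 * arg.sum(-1))


def make_phantom(spec: PhantomSpec):
    """Generate (tomo, mask, surface_truth, particle_truth, mesh).

    ``surface_truth`` holds exact mid-surface points; ``particle_truth`` has
    columns X, Y, Z (blob center), nx, ny, nz (outward normal) and psi
    (in-plane angle in the normal's projection basis, degrees).
    """
    rng = np.random.default_rng(spec.seed)
    geom = _Geometry(spec)
    nx, ny, nz = spec.dims
    X, Y, Z = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                          np.arange(nz, dtype=float), indexing="ij")
    d, _ = geom.signed_distance_and_normal(X, Y, Z)
    w = geom.patch_weight(X, Y, Z)
    sep, lw = spec.bilayer_separation, spec.leaflet_width
    density = -spec.membrane_amp * w * (
        np.exp(-0.5 * ((d - sep / 2) / lw) ** 2) + np.exp(-0.5 * ((d + sep / 2) / lw) ** 2))

    halfwidth = spec.mask_halfwidth if spec.mask_halfwidth is not None else sep / 2 + lw
    mask = ((np.abs(d) <= halfwidth) & (w > 0)).astype(np.float32)

    # particles
    truth_rows = []
    if spec.n_particles > 0:
        if spec.placement == "grid":
            grid_pts, grid_n = geom.grid_surface_points(rng, spec.n_particles,
                                                        spec.min_separation)
            queue = list(zip(grid_pts, grid_n))
        placed: list[np.ndarray] = []
        tries = 0
        while len(placed) < spec.n_particles:
            tries += 1
            if tries > 200 * spec.n_particles:
                raise RuntimeError("could not place particles with the requested separation")
            if spec.placement == "grid":
                p, n = queue[len(placed)]
            else:
                p, n = geom.random_surface_points(rng, 1)
                p, n = p[0], n[0]
                if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < spec.min_separation:
                    continue
            placed.append(p)
            psi = rng.uniform(0.0, 360.0)
            e1, e2 = projection_basis(n)
            dirv = np.cos(np.radians(psi)) * e1 + np.sin(np.radians(psi)) * e2
            cen = p + spec.particle_offset * n
            axes = np.stack([dirv, np.cross(n, dirv), n])
            _add_blob(density, cen, axes, np.array(spec.blob_sigmas), spec.particle_amp)
            _add_blob(density, cen + spec.satellite_offset * dirv,
                      np.eye(3), np.full(3, spec.satellite_sigma), spec.satellite_amp)
            truth_rows.append({"X": cen[0], "Y": cen[1], "Z": cen[2],
                               "nx": n[0], "ny": n[1], "nz": n[2], "psi": psi})

    if spec.noise_sigma > 0:
        density = density + rng.normal(0.0, spec.noise_sigma, size=density.shape)
    if spec.wedge_tilt_deg is not None:
        density = apply_wedge(density, spec.wedge_tilt_deg)

    tomo = VoxelVolume(density.astype(np.float32), voxel_size=spec.voxel_size)
    mask_vol = VoxelVolume(mask, voxel_size=spec.voxel_size)
    pts, _ = geom.sample_surface()
    surface_truth = PointSet(points=pts, label="surface_truth")
    truth = pd.DataFrame(truth_rows, columns=["X", "Y", "Z", "nx", "ny", "nz", "psi"])
    mesh = geom.make_mesh() if spec.make_mesh else None
    return tomo, mask_vol, surface_truth, truth, mesh
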
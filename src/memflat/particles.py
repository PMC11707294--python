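"""Particle analysis: from flattened-space picks to STA-ready metadata.

Covers score-based duplicate removal of per-slice picks, raw/flattened
coordinate conversion with membrane normals attached, construction of full
rotation matrices (membrane normal = particle z axis, user- or
classification-derived in-plane direction = particle x axis), ZYZ Euler
angles, normal-direction projection images, and simplified 3D/2D missing-
wedge CTF weights for classification.

Also provides a simple per-slice dark-blob picker and exhaustive rotational
template matching.  Both are synthetic stand-ins for the external neural
picker and 2D-classification programs of the full workflow; they exist so
that the geometry pipeline can be exercised end-to-end on phantom data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from skimage.feature import peak_local_max

from .flattening import FlatMap, _interp_SN, flat_to_raw
from .volio import VoxelVolume

__all__ = [
    "WedgeCTF",
    "ProjectionSpec",
    "dedup_picks",
    "attach_geometry",
    "orientation_matrix",
    "matrix_to_euler",
    "euler_to_matrix",
    "projection_basis",
    "project_particle",
    "build_3dctf",
    "extract_2dctf",
    "inplane_from_class2d",
    "find_blob_picks",
    "match_template_rotation",
    "refine_center_of_mass",
]


@dataclass
class ProjectionSpec:
    """Geometry of a normal-direction projection image."""

    box: int = 70
    depth: int = 7

    def __post_init__(self) -> None:
        if self.depth % 2 == 0:
            raise ValueError("projection depth must be odd (centered on the particle)")


@dataclass
class WedgeCTF:
    """Fourier-space weighting cube (DC at the center voxel) encoding the
    missing wedge and, optionally, per-tilt CTF values."""

    ctf3d: np.ndarray
    tilt_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    tilts: np.ndarray = field(default_factory=lambda: np.zeros(1))

    @property
    def size(self) -> int:
        return self.ctf3d.shape[0]


# ---------------------------------------------------------------------------
# Picks


def dedup_picks(picks: pd.DataFrame, min_spacing: float,
                min_score: float | None = None,
                max_count: int | None = None,
                use_w: bool = True) -> pd.DataFrame:
    """Greedy score-ranked duplicate removal of flattened-space picks.

    Picks are sorted by score descending (ties by (w, u, v) ascending); a
    pick survives iff its distance in flattened voxel space to every
    already-kept pick is >= ``min_spacing``.  Afterwards picks below
    ``min_score`` are dropped and the list truncated to ``max_count``.
    Output is independent of input order.
    """
    df = picks.copy()
    order = df.sort_values(["score", "w", "u", "v"],
                           ascending=[False, True, True, True],
                           kind="mergesort").index
    cols = ["u", "v", "w"] if use_w else ["u", "v"]
    coords = df.loc[order, cols].to_numpy(float)
    kept_idx: list[int] = []
    kept_pts: list[np.ndarray] = []
    tree = None
    for i, p in enumerate(coords):
        if kept_pts:
            if tree is None or len(kept_pts) % 64 == 0:
                tree = cKDTree(np.array(kept_pts))
            cand = tree.query_ball_point(p, r=min_spacing + 1e-9)
            ok = not cand
            if ok and len(kept_pts) > tree.n:
                recent = np.array(kept_pts[tree.n:])
                ok = np.all(np.linalg.norm(recent - p, axis=1) >= min_spacing)
            if not ok:
                continue
        kept_idx.append(order[i])
        kept_pts.append(p)
    out = df.loc[kept_idx]
    if min_score is not None:
        out = out[out["score"] >= min_score]
    if max_count is not None:
        out = out.iloc[:max_count]
    return out.reset_index(drop=True)


def attach_geometry(picks: pd.DataFrame, flatmap: FlatMap) -> pd.DataFrame:
    """Fill raw coordinates and membrane normals from flattened positions.

    raw = flat_to_raw(u, v, w); normal = bilinearly interpolated N(u, v).
    Picks outside the flatmap grid are dropped (with a warning)."""
    df = picks.copy().reset_index(drop=True)
    nu, nv = flatmap.shape
    inside = (df["u"].to_numpy() >= 0) & (df["u"].to_numpy() <= nu - 1) \
        & (df["v"].to_numpy() >= 0) & (df["v"].to_numpy() <= nv - 1)
    if not inside.all():
        warnings.warn(f"dropped {int((~inside).sum())} picks outside the flatmap grid",
                      stacklevel=2)
        df = df[inside].reset_index(drop=True)
    uvw = df[["u", "v", "w"]].to_numpy(float)
    raw = np.atleast_2d(flat_to_raw(flatmap, uvw))
    _, N = _interp_SN(flatmap, uvw[:, 0], uvw[:, 1])
    df[["X", "Y", "Z"]] = raw
    df[["nx", "ny", "nz"]] = N
    return df


# ---------------------------------------------------------------------------
# Orientations


def orientation_matrix(normal: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rotation matrix with columns (vx, vy, n).

    The user-labeled in-plane direction is first replaced by its component
    perpendicular to the membrane normal, then vy = n x vx completes a
    right-handed orthonormal triple.
    """
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    vx = np.asarray(direction, float)
    vx = vx - (vx @ n) * n
    norm = np.linalg.norm(vx)
    if norm < 1e-6:
        raise ValueError("direction degenerate with normal (parallel vectors)")
    vx = vx / norm
    vy = np.cross(n, vx)
    return np.column_stack([vx, vy, n])


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic Euler angles (degrees, STAR rot/tilt/psi) to a matrix."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Proper rotation matrix to ZYZ intrinsic (rot, tilt, psi) in degrees.

    Gimbal cases (tilt ~ 0 or 180) are canonicalized with psi = 0.
    """
    R = np.asarray(R, float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    c = np.clip(R[2, 2], -1.0, 1.0)
    if abs(c - 1.0) < 1e-12:
        return float(np.degrees(np.arctan2(R[1, 0], R[0, 0]))), 0.0, 0.0
    if abs(c + 1.0) < 1e-12:
        return float(np.degrees(np.arctan2(-R[1, 0], -R[0, 0]))), 180.0, 0.0
    tilt = np.degrees(np.arccos(c))
    rot = np.degrees(np.arctan2(R[1, 2], R[0, 2]))
    psi = np.degrees(np.arctan2(R[2, 1], -R[2, 0]))
    return float(rot), float(tilt), float(psi)


def projection_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis (e1, e2) perpendicular to ``direction``.

    e1 = normalize(d x z_hat) when defined, else x_hat; e2 = d x e1.  The
    same basis is shared by projection images and 2DCTF extraction so that
    in-plane angles are interpretable across both.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    cz = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(cz) > 1e-3:
        e1 = cz / np.linalg.norm(cz)
    else:
        e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(d, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# Projection images


def project_particle(tomo: VoxelVolume, center: np.ndarray, direction: np.ndarray,
                     spec: ProjectionSpec | None = None,
                     fill: float = 0.0) -> tuple[np.ndarray, bool]:
    """Project a particle along ``direction`` into a 2D image.

    image(i, j) = sum over depth samples t of the trilinear sample at
    center + (i - c) e1 + (j - c) e2 + t d, with c = (box - 1) / 2 and
    t in {-(depth-1)/2, ..., +(depth-1)/2}.  Returns (image, fully_inside).
    """
    spec = spec or ProjectionSpec()
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1, e2 = projection_basis(d)
    center = np.asarray(center, float)
    dims = np.array(tomo.data.shape, float)
    if np.any(center < 0) or np.any(center > dims - 1):
        raise ValueError("particle center outside the tomogram")
    c = (spec.box - 1) / 2.0
    i = np.arange(spec.box) - c
    ts = np.arange(spec.depth) - (spec.depth - 1) / 2.0
    pos = (center[None, None, None, :]
           + i[:, None, None, None] * e1[None, None, None, :]
           + i[None, :, None, None] * e2[None, None, None, :]
           + ts[None, None, :, None] * d[None, None, None, :])
    inside = np.all((pos >= 0) & (pos <= dims - 1), axis=-1)
    vals = ndimage.map_coordinates(tomo.data.astype(float), pos.reshape(-1, 3).T,
                                   order=1, mode="constant", cval=fill)
    img = vals.reshape(pos.shape[:3]).sum(axis=2)
    return img, bool(inside.all())


# ---------------------------------------------------------------------------
# Missing-wedge weighting


def _ctf1d(q_invA: np.ndarray, defocus_A: float, voltage_kV: float = 300.0,
           cs_mm: float = 2.7, amplitude_contrast: float = 0.07) -> np.ndarray:
    """Standard 1D CTF (underfocus positive, in Angstrom units)."""
    lam = 12.2639 / np.sqrt(voltage_kV * 1e3 + 0.97845e-6 * (voltage_kV * 1e3) ** 2)
    cs = cs_mm * 1e7
    chi = np.pi * lam * q_invA**2 * defocus_A - 0.5 * np.pi * cs * lam**3 * q_invA**4
    A = amplitude_contrast
    return -(np.sqrt(1 - A**2) * np.sin(chi) + A * np.cos(chi))


def build_3dctf(size: int, tilts_deg, tilt_axis=(0.0, 1.0, 0.0),
                ctf_params: dict | None = None, voxel_size: float = 1.0,
                slab_halfwidth: float = 1.0) -> WedgeCTF:
    """Build a simplified 3DCTF cube (DC at the center voxel).

    Each tilt contributes a planar slab through the origin perpendicular to
    its beam direction (the tilt rotates z_hat about ``tilt_axis``), with a
    linear falloff of half-width ``slab_halfwidth`` Fourier voxels.  The
    voxel weight is the maximum over tilts (keeping weights <= 1), optionally
    multiplied by the 1D CTF of the nearest (strongest-slab) tilt.  The
    result is Hermitian-symmetric by construction.

    This is a deliberately simple model of the per-particle 3DCTF produced
    by STA packages: no dose weighting or defocus gradients.
    """
    tilts = np.atleast_1d(np.asarray(tilts_deg, float))
    if tilts.size == 0:
        raise ValueError("tilt list is empty")
    axis = np.asarray(tilt_axis, float)
    axis = axis / np.linalg.norm(axis)
    c = size // 2
    q = np.stack(np.meshgrid(*([np.arange(size) - c] * 3), indexing="ij"), axis=-1).astype(float)

    beams = Rotation.from_rotvec(np.radians(tilts)[:, None] * axis[None, :]).apply([0.0, 0.0, 1.0])
    qdot = np.abs(np.tensordot(q, beams.T, axes=1))   # (size,size,size,ntilt)
    kern = np.maximum(0.0, 1.0 - qdot / slab_halfwidth)
    best = np.argmax(kern, axis=-1)
    weight = np.take_along_axis(kern, best[..., None], axis=-1)[..., 0]

    if ctf_params is not None:
        qmag = np.linalg.norm(q, axis=-1) / (size * voxel_size)  # 1/A
        defocus = ctf_params.get("defocus_A", 3e4)
        per_tilt = ctf_params.get("defocus_per_tilt")
        if per_tilt is not None:
            ctfs = np.stack([_ctf1d(qmag, d,
                                    ctf_params.get("voltage_kV", 300.0),
                                    ctf_params.get("cs_mm", 2.7),
                                    ctf_params.get("amplitude_contrast", 0.07))
                             for d in per_tilt], axis=-1)
            ctf = np.take_along_axis(ctfs, best[..., None], axis=-1)[..., 0]
        else:
            ctf = _ctf1d(qmag, defocus,
                         ctf_params.get("voltage_kV", 300.0),
                         ctf_params.get("cs_mm", 2.7),
                         ctf_params.get("amplitude_contrast", 0.07))
        weight = weight * ctf
    return WedgeCTF(ctf3d=weight, tilt_axis=axis, tilts=tilts)


def extract_2dctf(wedge: WedgeCTF, direction: np.ndarray, box: int | None = None) -> np.ndarray:
    """Central slice of the 3DCTF perpendicular to the projection direction.

    Shares ``projection_basis(direction)`` with ``project_particle`` so the
    image axes of the 2DCTF line up with the projection's.  Trilinear
    sampling of the cube; frequencies scale by size/box when box != size.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1, e2 = projection_basis(d)
    size = wedge.size
    box = size if box is None else box
    scale = size / box
    c_img = (box - 1) / 2.0
    c_cube = size // 2
    i = (np.arange(box) - c_img) * scale
    pos = (i[:, None, None] * e1[None, None, :] + i[None, :, None] * e2[None, None, :]) + c_cube
    vals = ndimage.map_coordinates(wedge.ctf3d, pos.reshape(-1, 3).T,
                                   order=1, mode="constant", cval=0.0)
    return vals.reshape(box, box)


# ---------------------------------------------------------------------------
# 2D-classification import


def inplane_from_class2d(picks: pd.DataFrame,
                         assignments: pd.DataFrame,
                         class_offsets: dict[int, tuple[float, float, float]] | None = None
                         ) -> pd.DataFrame:
    """Convert 2D-classification output into full orientations and 3D shifts.

    ``assignments`` carries per-pick (class_id, psi [deg], du, dv).  Optional
    per-class offsets (dpsi, du, dv) are added first.  For each pick the
    in-plane direction is cos(psi') e1 + sin(psi') e2 in the normal's
    projection basis; the rotation matrix, ZYZ Euler angles and the raw-frame
    shift (du' e1 + dv' e2) are attached.  Picks with a class that has no
    offset entry when offsets are given are dropped.
    """
    class_offsets = class_offsets or {}
    df = picks.reset_index(drop=True).copy()
    asg = assignments.reset_index(drop=True)
    if len(asg) != len(df):
        raise ValueError("assignments and picks must align row-wise")
    rows = []
    for i in range(len(df)):
        cls = int(asg.loc[i, "class_id"])
        if class_offsets and cls not in class_offsets:
            warnings.warn(f"pick {i}: unknown class {cls}, dropped", stacklevel=2)
            continue
        dpsi, du_off, dv_off = class_offsets.get(cls, (0.0, 0.0, 0.0))
        psi = float(asg.loc[i, "psi"]) + dpsi
        du = float(asg.loc[i, "du"]) + du_off
        dv = float(asg.loc[i, "dv"]) + dv_off
        n = df.loc[i, ["nx", "ny", "nz"]].to_numpy(float)
        e1, e2 = projection_basis(n)
        direction = np.cos(np.radians(psi)) * e1 + np.sin(np.radians(psi)) * e2
        R = orientation_matrix(n, direction)
        rot, tilt, spsi = matrix_to_euler(R)
        shift = du * e1 + dv * e2
        row = df.loc[i].to_dict()
        row.update({"class_id": cls, "dx": direction[0], "dy": direction[1],
                    "dz": direction[2], "rot": rot, "tilt": tilt, "psi": spsi,
                    "shift_x": shift[0], "shift_y": shift[1], "shift_z": shift[2]})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference picker / matcher (synthetic stand-ins for external neural
# pickers and 2D-classification programs)


def find_blob_picks(flat: VoxelVolume, w_range: tuple[int, int],
                    min_distance: int = 5, threshold_rel: float = 0.2,
                    dark: bool = True) -> pd.DataFrame:
    """Per-slice blob picking in a flattened tomogram.

    For every w slice in [w_range), 2D local extrema (dark blobs by default)
    become picks with the peak amplitude as score; duplicates across slices
    are left for ``dedup_picks``.  A simple reference picker standing in for
    an external neural detector.
    """
    rows = []
    for w in range(*w_range):
        sl = flat.data[:, :, w].astype(float)
        img = -sl if dark else sl
        img = img - np.median(img)
        if img.max() <= 0:
            continue
        peaks = peak_local_max(img, min_distance=min_distance,
                               threshold_abs=threshold_rel * img.max())
        for (u, v) in peaks:
            rows.append({"u": float(u), "v": float(v), "w": float(w),
                         "score": float(img[u, v])})
    return pd.DataFrame(rows, columns=["u", "v", "w", "score"])


def match_template_rotation(image: np.ndarray, template: np.ndarray,
                            step_deg: float = 1.0) -> tuple[float, float]:
    """Exhaustive in-plane rotational matching of a projection image.

    Rotates the template over [0, 360) and reports the angle maximizing the
    normalized cross-correlation (plus that correlation).  The angle is the
    rotation that maps template features onto image features, measured in the
    shared (e1, e2) projection basis.
    """
    img = image - image.mean()
    s = img.std()
    if s == 0:
        return 0.0, 0.0
    img = img / s
    best = (0.0, -np.inf)
    for ang in np.arange(0.0, 360.0, step_deg):
        rot = rotate_template(template, ang)
        rot = rot - rot.mean()
        rs = rot.std()
        if rs == 0:
            continue
        cc = float((img * rot).mean() / rs)
        if cc > best[1]:
            best = (float(ang), cc)
    return best


def rotate_template(template: np.ndarray, psi_deg: float) -> np.ndarray:
    """Rotate a template so a feature along +e1 moves to in-plane angle psi."""
    return ndimage.rotate(template, psi_deg, reshape=False, order=1, mode="nearest")


def estimate_shift(image: np.ndarray, template: np.ndarray, psi_deg: float,
                   upsample: int = 10) -> np.ndarray:
    """Sub-pixel (du, dv) displacement of the particle in the projection basis.

    Registers the psi-rotated template against the image by phase correlation;
    the returned shift is the particle's offset from the image center along
    (e1, e2), directly consumable as a 2D-classification displacement.
    """
    from skimage.registration import phase_cross_correlation

    rot = rotate_template(template, psi_deg)
    shift, _, _ = phase_cross_correlation(image, rot, upsample_factor=upsample,
                                          normalization=None)
    return np.asarray(shift, float)


def match_template_rotation_shift(image: np.ndarray, template: np.ndarray,
                                  step_deg: float = 2.0, max_shift: float = 6.0
                                  ) -> tuple[float, np.ndarray, float]:
    """Joint exhaustive search over in-plane rotation and 2D shift.

    For every rotation angle the cross-correlation map over shifts is taken
    by FFT; the global (angle, shift) maximizer of the normalized correlation
    is returned as (psi_deg, (du, dv), cc).  The shift is the particle's
    offset from the image center in the (e1, e2) projection basis.
    """
    img = image - image.mean()
    si = img.std()
    if si == 0:
        return 0.0, np.zeros(2), 0.0
    n = image.shape[0]
    F = np.fft.fft2(img)
    freqs = np.fft.fftfreq(n) * n
    allowed = (np.abs(freqs)[:, None] <= max_shift) & (np.abs(freqs)[None, :] <= max_shift)
    best = (0.0, np.zeros(2), -np.inf)
    for ang in np.arange(0.0, 360.0, step_deg):
        rot = rotate_template(template, ang)
        rot = rot - rot.mean()
        sr = rot.std()
        if sr == 0:
            continue
        cc_map = np.real(np.fft.ifft2(F * np.conj(np.fft.fft2(rot)))) / (si * sr * img.size)
        cc_map[~allowed] = -np.inf
        k = np.unravel_index(np.argmax(cc_map), cc_map.shape)
        cc = float(cc_map[k])
        if cc > best[2]:
            best = (float(ang), np.array([freqs[k[0]], freqs[k[1]]]), cc)
    return best


def align_particle(tomo: VoxelVolume, pos: np.ndarray, normal: np.ndarray,
                   template: np.ndarray, spec: ProjectionSpec | None = None,
                   n_iter: int = 2, step_deg: float = 2.0,
                   max_shift: float = 6.0) -> tuple[np.ndarray, float, float]:
    """Refine a particle position and in-plane angle by template matching.

    Projects along the (fixed) membrane normal, jointly matches rotation and
    shift, moves the position by the shift expressed in the projection basis,
    and repeats; a final sub-pixel shift estimate polishes the position.
    Returns (refined_position, psi_deg, cc).
    """
    spec = spec or ProjectionSpec()
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    e1, e2 = projection_basis(n)
    p = np.asarray(pos, float).copy()
    psi, cc = 0.0, 0.0
    for it in range(n_iter):
        img, _ = project_particle(tomo, p, n, spec)
        psi, shift, cc = match_template_rotation_shift(img, template, step_deg, max_shift)
        p = p + shift[0] * e1 + shift[1] * e2
    img, _ = project_particle(tomo, p, n, spec)
    sub = estimate_shift(img, template, psi)
    sub = np.clip(sub, -2.0, 2.0)
    p = p + sub[0] * e1 + sub[1] * e2
    return p, psi, cc


def refine_center_of_mass(tomo: VoxelVolume, pos: np.ndarray, radius: int = 4,
                          dark: bool = True, n_iter: int = 3) -> np.ndarray:
    """Sub-voxel position refinement by local (negated-density) center of mass."""
    p = np.asarray(pos, float).copy()
    dims = tomo.data.shape
    for _ in range(n_iter):
        lo = np.maximum(np.round(p).astype(int) - radius, 0)
        hi = np.minimum(np.round(p).astype(int) + radius + 1, dims)
        box = tomo.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
        box = -box if dark else box.copy()
        box -= box.min()
        if box.sum() == 0:
            return p
        com = np.array(ndimage.center_of_mass(box))
        p = lo + com
    return p
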
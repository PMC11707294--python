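"""Volume, mesh and table I/O plus the shared in-memory data model.

Conventions used throughout the package:

* Volumes are indexed ``data[x, y, z]`` (X fastest on disk, Z slowest),
  regardless of the on-disk MRC section order.
* Voxel coordinates are 0-based; the center of voxel ``(0, 0, 0)`` is the
  position ``(0.0, 0.0, 0.0)``.  STAR export documents this so 1-based
  consumers can shift.
* Voxel sizes are isotropic (anisotropic headers are rejected).
* All angles in tables are degrees.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import mrcfile
import numpy as np
import pandas as pd

__all__ = [
    "VoxelVolume",
    "PointSet",
    "ParamMesh",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "read_points",
    "write_points",
    "read_particles",
    "write_particles",
    "read_star",
    "write_star",
    "PARTICLE_COLUMNS",
    "STAR_COLUMNS",
]

#: Canonical particle-table columns (all optional except position):
#: flattened coords (u, v, w), raw coords (X, Y, Z), picking score,
#: membrane normal (nx, ny, nz), in-plane direction (dx, dy, dz),
#: Euler angles (rot, tilt, psi) in the ZYZ intrinsic convention, class id.
PARTICLE_COLUMNS = (
    "u", "v", "w", "X", "Y", "Z", "score",
    "nx", "ny", "nz", "dx", "dy", "dz",
    "rot", "tilt", "psi", "class_id",
)

STAR_COLUMNS = {
    "X": "rlnCoordinateX",
    "Y": "rlnCoordinateY",
    "Z": "rlnCoordinateZ",
    "rot": "rlnAngleRot",
    "tilt": "rlnAngleTilt",
    "psi": "rlnAnglePsi",
    "score": "rlnAutopickFigureOfMerit",
    "class_id": "rlnClassNumber",
}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with an isotropic voxel size.

    ``data`` is indexed ``[x, y, z]``; ``dims == data.shape``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


@dataclass
class PointSet:
    """A labelled set of 3D points in raw voxel coordinates, shape (n, 3)."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]


@dataclass
class ParamMesh:
    """A UV-parameterized triangle mesh: one (u, v) texture coordinate per vertex."""

    vertices: np.ndarray   # (n, 3)
    faces: np.ndarray      # (m, 3) int, 0-based
    texcoords: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        self.texcoords = np.asarray(self.texcoords, dtype=float).reshape(-1, 2)
        if len(self.texcoords) != len(self.vertices):
            raise FormatError("mesh not parameterized: texcoord count != vertex count")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise FormatError("face references invalid vertex index")

    def validate(self) -> None:
        """Reject degenerate faces (zero area in 3D or in (u, v) space)."""
        v, f, t = self.vertices, self.faces, self.texcoords
        a3 = np.linalg.norm(np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1)
        e1 = t[f[:, 1]] - t[f[:, 0]]
        e2 = t[f[:, 2]] - t[f[:, 0]]
        a2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
        if np.any(a3 <= 0) or np.any(a2 <= 0):
            raise FormatError("mesh contains degenerate (zero-area) faces")


# ---------------------------------------------------------------------------
# MRC volumes

_ACCEPTED_MODES = (0, 1, 2, 6)


def read_volume(path) -> VoxelVolume:
    """Read an MRC2014 volume.

    The data model stores X fastest / Z slowest; mrcfile returns ``[z, y, x]``,
    so the array is transposed on the way in.  Modes 0/1/2/6 are accepted and
    promoted to float32.  Anisotropic voxel sizes are rejected.
    """
    try:
        with mrcfile.open(str(path), permissive=False) as mrc:
            mode = int(mrc.header.mode)
            if mode not in _ACCEPTED_MODES:
                raise FormatError(f"unsupported MRC mode {mode} (accepted: {_ACCEPTED_MODES})")
            vs = mrc.voxel_size
            vx, vy, vz = float(vs.x), float(vs.y), float(vs.z)
            data = np.asarray(mrc.data)
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"malformed MRC header: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a single 3D volume, got ndim={data.ndim}")
    if vx <= 0:
        vx = vy = vz = 1.0
    if not (abs(vx - vy) < 1e-4 * vx and abs(vx - vz) < 1e-4 * vx):
        raise FormatError(
            f"anisotropic voxel size ({vx:g}, {vy:g}, {vz:g}) not supported; "
            "all geometry assumes one isotropic pixel unit"
        )
    vol = VoxelVolume(
        data=np.ascontiguousarray(data.transpose(2, 1, 0)).astype(np.float32, copy=False),
        voxel_size=vx,
    )
    return vol


def write_volume(vol: VoxelVolume, path) -> None:
    """Write a volume as MRC2014 mode 2 (32-bit float) with recomputed stats."""
    vol.validate()
    data = np.ascontiguousarray(vol.data.transpose(2, 1, 0)).astype(np.float32, copy=False)
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(data)
        mrc.voxel_size = vol.voxel_size
        mrc.update_header_from_data()
        mrc.update_header_stats()


# ---------------------------------------------------------------------------
# Wavefront OBJ meshes (v / vt / f v/vt records)

def read_mesh(path) -> ParamMesh:
    """Read a parameterized OBJ mesh.

    OBJ keeps separate index spaces for positions and texture coordinates;
    corners are split so that every output vertex carries exactly one (u, v).
    Faces without texture indices raise ``FormatError("mesh not parameterized")``.
    """
    positions: list[list[float]] = []
    texcoords: list[list[float]] = []
    corners: list[tuple[int, int]] = []
    faces: list[list[int]] = []
    corner_index: dict[tuple[int, int], int] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                positions.append([float(x) for x in parts[1:4]])
            elif tag == "vt":
                texcoords.append([float(x) for x in parts[1:3]])
            elif tag == "f":
                if len(parts) != 4:
                    raise FormatError(f"line {lineno}: only triangle faces supported")
                face = []
                for corner in parts[1:]:
                    fields = corner.split("/")
                    if len(fields) < 2 or not fields[1]:
                        raise FormatError(f"line {lineno}: mesh not parameterized (face lacks texture index)")
                    vi, ti = int(fields[0]) - 1, int(fields[1]) - 1
                    key = (vi, ti)
                    if key not in corner_index:
                        corner_index[key] = len(corners)
                        corners.append(key)
                    face.append(corner_index[key])
                faces.append(face)

    if not faces:
        raise FormatError("OBJ contains no faces")
    if len(positions) == len(texcoords) and all(vi == ti for vi, ti in corners):
        # 1:1 v/vt indexing (our own writer's layout): keep vertex order as-is
        return ParamMesh(vertices=np.asarray(positions, float),
                         faces=np.array([[corners[c][0] for c in f] for f in faces]),
                         texcoords=np.asarray(texcoords, float))
    verts = np.array([positions[vi] for vi, _ in corners], dtype=float)
    tcs = np.array([texcoords[ti] for _, ti in corners], dtype=float)
    return ParamMesh(vertices=verts, faces=np.array(faces, dtype=int), texcoords=tcs)


def write_mesh(mesh: ParamMesh, path) -> None:
    """Write a ParamMesh as OBJ with ``f v/vt`` faces (winding preserved)."""
    buf = io.StringIO()
    for v in mesh.vertices:
        buf.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    for t in mesh.texcoords:
        buf.write(f"vt {t[0]:.9g} {t[1]:.9g}\n")
    for f in mesh.faces:
        i, j, k = (int(x) + 1 for x in f)
        buf.write(f"f {i}/{i} {j}/{j} {k}/{k}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Point and particle tables

def _read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#", **kwargs)
    except ValueError as exc:
        raise FormatError(f"cannot parse table {path}: {exc}") from exc


def read_points(path, label: str = "") -> PointSet:
    """Read a whitespace/comma table of X, Y, Z voxel coordinates."""
    df = _read_table(path, header=None)
    first = df.iloc[0]
    if first.apply(lambda x: isinstance(x, str)).any():
        df = _read_table(path)  # had a header row
    arr = df.to_numpy()
    if arr.shape[1] < 3:
        raise FormatError(f"point table needs >= 3 columns, got {arr.shape[1]}")
    try:
        pts = arr[:, :3].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in point table: {exc}") from exc
    if not np.all(np.isfinite(pts)):
        bad = int(np.where(~np.isfinite(pts).all(axis=1))[0][0]) + 1
        raise FormatError(f"non-numeric cell in point table at data line {bad}")
    return PointSet(points=pts, label=label)


def write_points(points: PointSet, path) -> None:
    pd.DataFrame(points.points, columns=["X", "Y", "Z"]).to_csv(path, index=False)


def read_particles(path) -> pd.DataFrame:
    """Read a particle table (CSV/TSV with a header of canonical column names)."""
    df = _read_table(path)
    for col in df.columns:
        if col != "class_id" and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~pd.to_numeric(df[col], errors="coerce").notna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(f"non-numeric cell in column {col!r} at line {line}")
    return df


def write_particles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# STAR export/import (single-loop RELION dialect)

def write_star(df: pd.DataFrame, path, block: str = "particles") -> None:
    """Export particle metadata as a STAR loop.

    Coordinates are written 0-based (center of voxel (0,0,0) is 0.0); 1-based
    consumers should add 1.  Only columns with a known rln mapping are written.
    """
    cols = [c for c in STAR_COLUMNS if c in df.columns]
    if not cols:
        raise ValueError("no STAR-mappable columns present")
    lines = [f"data_{block}", "", "loop_"]
    for i, c in enumerate(cols, 1):
        lines.append(f"_{STAR_COLUMNS[c]} #{i}")
    for _, row in df.iterrows():
        fields = []
        for c in cols:
            v = row[c]
            fields.append(str(int(v)) if c == "class_id" else f"{float(v):.6f}")
        lines.append(" ".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_star(path) -> pd.DataFrame:
    """Read a single-loop STAR file back into canonical columns."""
    inverse = {v: k for k, v in STAR_COLUMNS.items()}
    names: list[str] = []
    rows: list[list[float]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                names = []
                continue
            if line.startswith("_"):
                tag = line.split()[0].lstrip("_")
                names.append(inverse.get(tag, tag))
                continue
            if in_loop:
                parts = line.split()
                if len(parts) != len(names):
                    raise FormatError(f"STAR row has {len(parts)} fields, expected {len(names)}")
                rows.append([float(x) for x in parts])
    if not names:
        raise FormatError("no STAR loop found")
    df = pd.DataFrame(rows, columns=names)
    if "class_id" in df.columns:
        df["class_id"] = df["class_id"].astype(int)
    return df
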
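"""Triangulated vascular-surface data model and I/O.

Everything downstream (WSS metrics, morphology) consumes the two containers
defined here:

* :class:`TriSurfaceMesh` — vertices/triangles in metres with a per-triangle
  region label (``dome`` / ``parent`` / ``other``) and an optional ordered
  neck-boundary vertex loop;
* :class:`TimeVaryingVectorField` — per-vertex wall-shear-stress vectors (Pa)
  sampled uniformly over one cardiac period.

Units are SI throughout (m, Pa, s); converters belong at I/O boundaries.

Supported formats: STL and OBJ (through :mod:`trimesh`) and VTK *legacy
ASCII* polydata (read/written natively; binary and XML VTK are out of
scope).  Time series are stored as one CSV per instant plus a plain-text
manifest, or as one VTK polydata per instant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh

from .exceptions import (
    DegenerateGeometryError,
    DimensionError,
    MeshFormatError,
    UnsupportedGeometryError,
)

__all__ = [
    "TriSurfaceMesh",
    "TimeVaryingVectorField",
    "GeometryTables",
    "read_mesh",
    "write_mesh",
    "geometry_tables",
    "project_tangential",
    "write_field_series",
    "read_field_series",
]

REGION_NAMES = ("dome", "parent", "other")
REGION_CODES = {name: i for i, name in enumerate(REGION_NAMES)}

#: triangles below this area (m²) are considered degenerate
_DEGENERATE_AREA = 1e-18


@dataclass
class TriSurfaceMesh:
    """Triangle surface mesh of an aneurysm sac and (optionally) parent vessel.

    Parameters
    ----------
    vertices : (n_v, 3) float array
        Vertex coordinates in metres.
    faces : (n_f, 3) int array
        Vertex index triples, counter-clockwise seen from outside the vessel.
    region : (n_f,) str array, optional
        Per-triangle label, one of ``dome``, ``parent``, ``other``.
        Defaults to all-``dome``.
    neck_loop : (k,) int array, optional
        Ordered vertex indices tracing the neck boundary.
    """

    vertices: np.ndarray
    faces: np.ndarray
    region: np.ndarray | None = None
    neck_loop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError("vertices must have shape (n_v, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise UnsupportedGeometryError("faces must be triangles (n_f, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise DimensionError("face index exceeds vertex count")
        if self.region is None:
            self.region = np.full(len(self.faces), "dome", dtype="U6")
        else:
            self.region = np.asarray(self.region, dtype="U6")
            if len(self.region) != len(self.faces):
                raise DimensionError("region label length != face count")
            bad = set(np.unique(self.region)) - set(REGION_NAMES)
            if bad:
                raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.neck_loop is not None:
            self.neck_loop = np.asarray(self.neck_loop, dtype=np.int64)

    # -- basic sizes ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- derived geometry (cached lazily) ---------------------------------
    def _tri_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    @property
    def face_cross(self) -> np.ndarray:
        """Unnormalised face normals (cross products), (n_f, 3)."""
        a, b, c = self._tri_points()
        return np.cross(b - a, c - a)

    @property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross, axis=1)

    @property
    def face_normals(self) -> np.ndarray:
        cross = self.face_cross
        nrm = np.linalg.norm(cross, axis=1, keepdims=True)
        areas = 0.5 * nrm[:, 0]
        if np.any(areas <= _DEGENERATE_AREA):
            idx = int(np.argmin(areas))
            raise DegenerateGeometryError(
                f"triangle {idx} has area {areas[idx]:.3e} m² (degenerate)"
            )
        return cross / nrm

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric (one-third) lumped vertex areas, m².

        Exactly conservative: ``vertex_areas.sum() == face_areas.sum()``.
        """
        va = np.zeros(self.n_vertices)
        third = self.face_areas / 3.0
        for k in range(3):
            np.add.at(va, self.faces[:, k], third)
        return va

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""
        vn = np.zeros_like(self.vertices)
        cross = self.face_cross  # |cross| = 2A, so this is area weighting
        for k in range(3):
            np.add.at(vn, self.faces[:, k], cross)
        nrm = np.linalg.norm(vn, axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        return vn / nrm

    @property
    def dome_faces(self) -> np.ndarray:
        """Boolean mask of faces labeled ``dome``."""
        return self.region == "dome"

    @property
    def dome_vertices(self) -> np.ndarray:
        """Boolean mask of vertices incident to at least one dome face."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[np.unique(self.faces[self.dome_faces])] = True
        return mask

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        areas = self.face_areas
        if np.any(areas <= _DEGENERATE_AREA):
            idx = int(np.argmin(areas))
            raise DegenerateGeometryError(
                f"triangle {idx} has area {areas[idx]:.3e} m² (degenerate)"
            )
        if not np.isfinite(self.vertices).all():
            raise ValueError("non-finite vertex coordinate")


@dataclass
class GeometryTables:
    """Per-face and per-vertex geometric quantities of a mesh."""

    face_areas: np.ndarray  # m²
    face_normals: np.ndarray  # unit
    vertex_areas: np.ndarray  # m²


@dataclass
class TimeVaryingVectorField:
    """Per-vertex WSS vectors τ (Pa) at uniform instants over one period.

    ``samples[i]`` is the (n_v, 3) field at time ``i * period / n_t``; the
    wrap-around sample at ``t = period`` equals sample 0 and is *not* stored.
    """

    samples: np.ndarray  # (n_t, n_v, 3), Pa
    period: float  # s
    tangency_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[2] != 3:
            raise DimensionError("samples must have shape (n_t, n_v, 3)")
        if self.n_t < 16:
            raise ValueError(f"need at least 16 time samples, got {self.n_t}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("non-finite field sample")

    @property
    def n_t(self) -> int:
        return self.samples.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_t) * (self.period / self.n_t)

    def check_tangent(self, mesh: TriSurfaceMesh) -> bool:
        """True if normal leakage is within ``tangency_tol`` everywhere."""
        normals = mesh.vertex_normals
        comp = np.abs(np.einsum("tvk,vk->tv", self.samples, normals))
        mag = np.linalg.norm(self.samples, axis=2)
        return bool(np.all(comp <= self.tangency_tol * np.maximum(mag, 1e-300)))


# ---------------------------------------------------------------------------
# geometric tables / tangential projection
# ---------------------------------------------------------------------------

def geometry_tables(mesh: TriSurfaceMesh) -> GeometryTables:
    """Face areas, unit face normals and barycentric vertex areas.

    Vertex area is one third of the summed areas of incident triangles, so
    the vertex-area total equals the face-area total to round-off.
    """
    return GeometryTables(
        face_areas=mesh.face_areas,
        face_normals=mesh.face_normals,
        vertex_areas=mesh.vertex_areas,
    )


def project_tangential(
    mesh: TriSurfaceMesh, samples: np.ndarray, period: float | None = None
) -> TimeVaryingVectorField | np.ndarray:
    """Remove the vertex-normal component from a per-vertex vector field.

    ``samples`` may be a single (n_v, 3) snapshot (returns an array) or an
    (n_t, n_v, 3) series (returns a :class:`TimeVaryingVectorField`; requires
    ``period``).  Magnitudes never increase.
    """
    arr = np.asarray(samples, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.shape[1] != mesh.n_vertices:
        raise DimensionError(
            f"field has {arr.shape[1]} vertices, mesh has {mesh.n_vertices}"
        )
    normals = mesh.vertex_normals
    comp = np.einsum("tvk,vk->tv", arr, normals)
    out = arr - comp[:, :, None] * normals[None]
    if single:
        return out[0]
    if period is None:
        raise ValueError("period required for a time series")
    return TimeVaryingVectorField(samples=out, period=period)


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("stl", "obj", "vtk"):
        return suffix
    raise MeshFormatError(f"cannot infer mesh format from {path.name!r}")


def read_mesh(path: str | Path, fmt: str | None = None) -> TriSurfaceMesh:
    """Read a triangle surface mesh (STL, OBJ or VTK legacy ASCII polydata).

    Region labels are taken from a cell-data array named ``region`` when
    present (VTK only); otherwise every triangle is labeled ``dome``.
    Winding is made consistent on read (with a warning if repairs occurred).
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        mesh = _read_vtk_polydata(path)[0]
    elif fmt in ("stl", "obj"):
        try:
            tm = trimesh.load(str(path), file_type=fmt, process=False)
        except Exception as exc:  # noqa: BLE001 - normalise loader failures
            raise MeshFormatError(f"cannot read {path}: {exc}") from exc
        if isinstance(tm, trimesh.Scene):
            geoms = list(tm.geometry.values())
            if not geoms:
                raise MeshFormatError(f"{path} contains no geometry")
            tm = geoms[0]
        if not isinstance(tm, trimesh.Trimesh):
            raise UnsupportedGeometryError(f"{path} is not a triangle mesh")
        mesh = TriSurfaceMesh(np.array(tm.vertices), np.array(tm.faces))
    else:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    _repair_winding(mesh)
    mesh.validate()
    return mesh


def _repair_winding(mesh: TriSurfaceMesh) -> None:
    """Make triangle winding consistent; warn when repairs were needed."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces.copy(), process=False)
    trimesh.repair.fix_winding(tm)
    flipped = int(np.sum(np.any(tm.faces != mesh.faces, axis=1)))
    if flipped:
        warnings.warn(
            f"repaired winding of {flipped} triangles for consistency",
            stacklevel=3,
        )
        mesh.faces = np.asarray(tm.faces, dtype=np.int64)
    # outward orientation for closed surfaces: positive signed volume
    if tm.is_watertight and tm.volume < 0:
        warnings.warn("flipped orientation to outward (signed volume)", stacklevel=3)
        mesh.faces = mesh.faces[:, ::-1]


def write_mesh(
    mesh: TriSurfaceMesh,
    path: str | Path,
    point_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write a mesh as VTK legacy ASCII polydata with optional point data.

    ``point_data`` maps array names to per-vertex scalars (n_v,) or vectors
    (n_v, 3).  The region labels go into an integer cell-data array
    ``region`` (0=dome, 1=parent, 2=other); ``read_mesh`` reverses the
    mapping, so a write/read round trip preserves labels.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    for name, arr in point_data.items():
        arr = np.asarray(arr, float)
        if arr.shape[0] != mesh.n_vertices:
            raise DimensionError(
                f"point array {name!r} has length {arr.shape[0]}, "
                f"expected {mesh.n_vertices}"
            )
        point_data[name] = arr
    lines = [
        "# vtk DataFile Version 3.0",
        "aneukit surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    lines.append(f"CELL_DATA {mesh.n_faces}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(REGION_CODES[r]) for r in mesh.region]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.17g}" for x in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.17g}" for x in v) for v in arr]
            else:
                raise DimensionError(f"point array {name!r} must be (n,) or (n, 3)")
    path.write_text("\n".join(lines) + "\n")


def _read_vtk_polydata(
    path: Path,
) -> tuple[TriSurfaceMesh, dict[str, np.ndarray]]:
    """Parse legacy ASCII VTK polydata; returns (mesh, point_data)."""
    tokens_iter = _VtkTokens(path)
    try:
        return _parse_vtk(tokens_iter)
    except (StopIteration, ValueError, IndexError, KeyError) as exc:
        raise MeshFormatError(f"cannot parse VTK file {path}: {exc}") from exc


class _VtkTokens:
    """Whitespace token stream over a text file."""

    def __init__(self, path: Path):
        text = path.read_text()
        if re.search(r"^BINARY\s*$", text, flags=re.M):
            raise MeshFormatError(f"{path}: binary VTK is not supported")
        # drop the two header lines (version comment + title)
        body = text.split("\n", 2)[2] if text.count("\n") >= 2 else ""
        self._tokens = body.split()
        self._pos = 0

    def next(self) -> str:
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok

    def take(self, n: int) -> list[str]:
        out = self._tokens[self._pos : self._pos + n]
        if len(out) != n:
            raise ValueError("unexpected end of file")
        self._pos += n
        return out

    def peek(self) -> str | None:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None


def _parse_vtk(tk: _VtkTokens) -> tuple[TriSurfaceMesh, dict[str, np.ndarray]]:
    if tk.next().upper() != "ASCII":
        raise MeshFormatError("expected ASCII VTK file")
    word = tk.next().upper()
    if word != "DATASET" or tk.next().upper() != "POLYDATA":
        raise MeshFormatError("expected DATASET POLYDATA")
    vertices = faces = None
    region = None
    point_data: dict[str, np.ndarray] = {}
    n_points = n_cells = 0
    section = None  # None | "point" | "cell"
    while (kw := tk.peek()) is not None:
        kw = kw.upper()
        tk.next()
        if kw == "POINTS":
            n_points = int(tk.next())
            tk.next()  # dtype
            vals = np.array(tk.take(3 * n_points), dtype=float)
            vertices = vals.reshape(n_points, 3)
        elif kw in ("POLYGONS", "TRIANGLE_STRIPS", "LINES", "VERTICES"):
            n_cells = int(tk.next())
            size = int(tk.next())
            vals = [int(t) for t in tk.take(size)]
            if kw != "POLYGONS":
                raise UnsupportedGeometryError(f"unsupported cell block {kw}")
            faces_list, i = [], 0
            while i < len(vals):
                k = vals[i]
                if k != 3:
                    raise UnsupportedGeometryError(
                        f"non-triangular cell with {k} vertices"
                    )
                faces_list.append(vals[i + 1 : i + 4])
                i += k + 1
            faces = np.array(faces_list, dtype=np.int64)
        elif kw == "POINT_DATA":
            section = "point"
            tk.next()  # count
        elif kw == "CELL_DATA":
            section = "cell"
            tk.next()  # count
        elif kw == "SCALARS":
            name = tk.next()
            tk.next()  # dtype
            ncomp_tok = tk.peek()
            ncomp = 1
            if ncomp_tok is not None and ncomp_tok.isdigit():
                ncomp = int(tk.next())
            if (tk.peek() or "").upper() == "LOOKUP_TABLE":
                tk.next()
                tk.next()
            count = n_points if section == "point" else n_cells
            vals = np.array(tk.take(ncomp * count), dtype=float)
            if section == "cell" and name == "region":
                codes = vals.astype(int)
                region = np.array([REGION_NAMES[c] for c in codes], dtype="U6")
            elif section == "point":
                point_data[name] = vals if ncomp == 1 else vals.reshape(count, ncomp)
        elif kw == "VECTORS":
            name = tk.next()
            tk.next()  # dtype
            count = n_points if section == "point" else n_cells
            vals = np.array(tk.take(3 * count), dtype=float).reshape(count, 3)
            if section == "point":
                point_data[name] = vals
        else:
            raise MeshFormatError(f"unsupported VTK keyword {kw!r}")
    if vertices is None or faces is None:
        raise MeshFormatError("VTK file lacks POINTS or POLYGONS")
    return TriSurfaceMesh(vertices, faces, region=region), point_data


def read_point_data(path: str | Path) -> dict[str, np.ndarray]:
    """Point-data arrays of a VTK legacy polydata file."""
    return _read_vtk_polydata(Path(path))[1]


# ---------------------------------------------------------------------------
# time-series I/O (one CSV per instant + plain-text manifest)
# ---------------------------------------------------------------------------

def write_field_series(
    mesh: TriSurfaceMesh,
    fld: TimeVaryingVectorField,
    directory: str | Path,
    fmt: str = "csv",
) -> None:
    """Persist a WSS time series under ``directory``.

    Layout: ``manifest.txt`` (``period``, ``n_t``, ``format``) plus either
    ``wss_####.csv`` files with columns ``x,y,z,tx,ty,tz`` or VTK polydata
    files carrying a ``wss`` point vector array.
    """
    if fld.n_vertices != mesh.n_vertices:
        raise DimensionError("field/mesh vertex count mismatch")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.txt").write_text(
        f"period: {fld.period:.17g}\nn_t: {fld.n_t}\nformat: {fmt}\n"
    )
    for i in range(fld.n_t):
        if fmt == "csv":
            data = np.hstack([mesh.vertices, fld.samples[i]])
            header = "x,y,z,tx,ty,tz"
            np.savetxt(
                directory / f"wss_{i:04d}.csv",
                data,
                delimiter=",",
                header=header,
                comments="",
            )
        elif fmt == "vtk":
            write_mesh(mesh, directory / f"wss_{i:04d}.vtk", {"wss": fld.samples[i]})
        else:
            raise ValueError(f"unknown series format {fmt!r}")


def read_field_series(directory: str | Path) -> TimeVaryingVectorField:
    """Load a WSS time series written by :func:`write_field_series`."""
    directory = Path(directory)
    manifest = {}
    for line in (directory / "manifest.txt").read_text().splitlines():
        if ":" in line:
            key, val = line.split(":", 1)
            manifest[key.strip()] = val.strip()
    period = float(manifest["period"])
    n_t = int(manifest["n_t"])
    fmt = manifest.get("format", "csv")
    samples = []
    for i in range(n_t):
        if fmt == "csv":
            data = np.loadtxt(
                directory / f"wss_{i:04d}.csv", delimiter=",", skiprows=1
            )
            samples.append(data[:, 3:6])
        elif fmt == "vtk":
            samples.append(read_point_data(directory / f"wss_{i:04d}.vtk")["wss"])
        else:
            raise MeshFormatError(f"unknown series format {fmt!r}")
    return TimeVaryingVectorField(np.array(samples), period=period)
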
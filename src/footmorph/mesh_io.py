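"""Mesh and landmark I/O plus geometric preprocessing.

Surface meshes travel as :class:`TriangleSurfaceMesh` (vertices in mm,
triangular faces, optional per-vertex scalar channel such as a signed
geometric-error map).  STL (ASCII and binary), PLY and OBJ are supported
through :mod:`trimesh`; PLY writing uses an in-package double-precision
ASCII writer so that coordinates and the per-vertex ``quality`` scalar
survive a round trip to 1e-6 mm.

Landmarks are named 3D points in a plain CSV dialect (``name,x,y,z`` with a
one-line header, mm units); JSON is accepted as an alternate carrier.

The coordinate convention used throughout the package is right-handed with
+z vertical (superior), +y anterior (toe direction), and +x medial for a
right foot; all lengths are millimetres.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleSurfaceMesh",
    "VolumeMesh",
    "LandmarkSet",
    "FOOT_LANDMARK_NAMES",
    "read_surface",
    "write_surface",
    "read_landmarks",
    "write_landmarks",
    "trim_surface",
]

#: Canonical 16-landmark foot schema, ordered posterior to anterior.
FOOT_LANDMARK_NAMES: tuple[str, ...] = (
    "posterior calcaneus",
    "central plantar heel",
    "heel medial",
    "heel lateral",
    "achilles tendon between malleoli",
    "malleolus medial",
    "malleolus lateral",
    "navicular tuberosity",
    "navicular dorsal",
    "fifth metatarsal basis",
    "first metatarsal head",
    "second tarsometatarsal dorsal",
    "third metatarsophalangeal plantar",
    "hallux tip",
    "second toe tip",
    "fifth toe tip",
)


@dataclass
class TriangleSurfaceMesh:
    """Triangle surface mesh in mm with an optional per-vertex scalar."""

    vertices: np.ndarray
    faces: np.ndarray
    scalar: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if len(self.faces):
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("face with repeated vertex index")
        if self.scalar is not None:
            self.scalar = np.ascontiguousarray(self.scalar, dtype=np.float64)
            if self.scalar.shape != (len(self.vertices),):
                raise ValueError("scalar channel must have one value per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def area(self) -> float:
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def with_vertices(self, vertices: np.ndarray) -> "TriangleSurfaceMesh":
        """Copy with replaced vertex coordinates (topology preserved)."""
        return TriangleSurfaceMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy(),
                                   None if self.scalar is None else self.scalar.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(),
                               process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh,
                     scalar: Optional[np.ndarray] = None) -> "TriangleSurfaceMesh":
        return cls(np.asarray(mesh.vertices, dtype=np.float64),
                   np.asarray(mesh.faces, dtype=np.int64), scalar)


@dataclass
class VolumeMesh:
    """Volume mesh: nodes plus tet4 / hex8 solid and tri3 membrane elements.

    ``element_sets`` maps a set name to ``(kind, indices)`` where *kind* is
    one of ``"tet4" | "hex8" | "tri3"`` and *indices* index into the
    corresponding connectivity array.  ``node_sets`` maps names to node
    index arrays.
    """

    nodes: np.ndarray
    tet4: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    hex8: np.ndarray = field(default_factory=lambda: np.zeros((0, 8), dtype=np.int64))
    tri3: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    element_sets: dict = field(default_factory=dict)
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tet4 = np.ascontiguousarray(self.tet4, dtype=np.int64).reshape(-1, 4)
        self.hex8 = np.ascontiguousarray(self.hex8, dtype=np.int64).reshape(-1, 8)
        self.tri3 = np.ascontiguousarray(self.tri3, dtype=np.int64).reshape(-1, 3)
        n = len(self.nodes)
        for name, conn in (("tet4", self.tet4), ("hex8", self.hex8), ("tri3", self.tri3)):
            if conn.size and (conn.min() < 0 or conn.max() >= n):
                raise ValueError(f"{name} connectivity index out of range")
        counts = {"tet4": len(self.tet4), "hex8": len(self.hex8), "tri3": len(self.tri3)}
        seen: dict = {}
        for set_name, (kind, idx) in self.element_sets.items():
            idx = np.asarray(idx, dtype=np.int64)
            if kind not in counts:
                raise ValueError(f"unknown element kind {kind!r} in set {set_name!r}")
            if idx.size and (idx.min() < 0 or idx.max() >= counts[kind]):
                raise ValueError(f"element set {set_name!r} indexes out of range")
            overlap = seen.setdefault(kind, set()).intersection(idx.tolist())
            if overlap:
                raise ValueError(f"element set {set_name!r} overlaps another set")
            seen[kind].update(idx.tolist())
            self.element_sets[set_name] = (kind, idx)

    @property
    def n_elements(self) -> int:
        return len(self.tet4) + len(self.hex8) + len(self.tri3)


@dataclass
class LandmarkSet:
    """Ordered, named 3D points (mm)."""

    names: Sequence[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(str(n) for n in self.names)
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise ValueError("names and points length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate landmark names")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite landmark coordinate")

    def __len__(self) -> int:
        return len(self.names)

    def corresponds_to(self, other: "LandmarkSet") -> bool:
        """True when both sets carry the same names in the same order."""
        return self.names == other.names

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self.names.index(name)]


# ---------------------------------------------------------------------------
# surface I/O

_FORMATS = ("stl", "ply", "obj")


def _infer_format(path: Path, format: Optional[str]) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported surface format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def _weld(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge bit-identical vertices (STL stores one triple per facet)."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def read_surface(path, format: Optional[str] = None) -> TriangleSurfaceMesh:
    """Read a triangle surface mesh from STL, PLY or OBJ.

    STL facets are welded (exactly coincident corner vertices merged); PLY
    per-vertex ``quality`` properties are loaded into the scalar channel.
    Quad or polygon faces are triangulated by the loader with a logged
    notice.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.is_file():
        raise IOError(f"surface file not found: {path}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - loader-specific messages
        raise IOError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if fmt == "obj":
        raw = path.read_text()
        if any(len(line.split()) > 4 for line in raw.splitlines()
               if line.startswith("f ")):
            logger.info("polygon faces in %s triangulated (fan, anchored at first vertex)", path)
    scalar = None
    if fmt == "ply":
        raw_ply = loaded.metadata.get("_ply_raw", {})
        vert_block = raw_ply.get("vertex", {})
        data = vert_block.get("data", {})
        if isinstance(data, dict) and "quality" in data:
            scalar = np.asarray(data["quality"], dtype=np.float64).ravel()
        elif getattr(data, "dtype", None) is not None and "quality" in (data.dtype.names or ()):
            scalar = np.asarray(data["quality"], dtype=np.float64).ravel()
    if fmt == "stl":
        vertices, faces = _weld(vertices, faces)
    return TriangleSurfaceMesh(vertices, faces, scalar)


def _write_ply_ascii(mesh: TriangleSurfaceMesh, path: Path, include_scalar: bool) -> None:
    # double-precision properties so round trips are exact to printing precision
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if include_scalar:
        lines.append("property double quality")
    lines += [
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for i, v in enumerate(mesh.vertices):
        row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
        if include_scalar:
            row += f" {mesh.scalar[i]:.17g}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def write_surface(mesh: TriangleSurfaceMesh, path, format: Optional[str] = None,
                  include_scalar: bool = False, binary: bool = False) -> Path:
    """Write a surface mesh.

    ``include_scalar`` requires PLY (the only supported carrier of a
    per-vertex scalar).  STL is written in ASCII unless ``binary`` is set;
    binary STL stores float32 coordinates and is therefore not exact to
    1e-6 mm at foot scale.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh")
    if include_scalar:
        if mesh.scalar is None:
            raise ValueError("include_scalar=True but mesh has no scalar channel")
        if fmt != "ply":
            raise ValueError(
                f"format {fmt.upper()} cannot carry a per-vertex scalar; use PLY")
    if fmt == "ply":
        _write_ply_ascii(mesh, path, include_scalar)
        return path
    tm = mesh.to_trimesh()
    if fmt == "stl":
        data = tm.export(file_type="stl" if binary else "stl_ascii")
    else:
        data = tm.export(file_type="obj")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return path


# ---------------------------------------------------------------------------
# landmark I/O

def read_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV (``name,x,y,z``, one header line) or JSON."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"landmark file not found: {path}")
    text = path.read_text()
    names: list[str] = []
    points: list[list[float]] = []
    if path.suffix.lower() == ".json" or text.lstrip().startswith(("{", "[")):
        payload = json.loads(text)
        entries = payload["landmarks"] if isinstance(payload, dict) else payload
        for entry in entries:
            names.append(entry["name"])
            points.append([float(c) for c in entry["point"]])
    else:
        rows = [line for line in text.splitlines() if line.strip()]
        for row in rows[1:]:  # skip header
            parts = [p.strip() for p in row.split(",")]
            if len(parts) != 4:
                raise ValueError(f"malformed landmark row: {row!r}")
            names.append(parts[0])
            points.append([float(p) for p in parts[1:]])
    return LandmarkSet(names, np.asarray(points, dtype=np.float64))


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    """Write landmarks; CSV by default, JSON when the path ends in .json."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"landmarks": [
            {"name": n, "point": [float(c) for c in p]}
            for n, p in zip(landmarks.names, landmarks.points)
        ]}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        lines = ["name,x,y,z"]
        for n, p in zip(landmarks.names, landmarks.points):
            lines.append(f"{n},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}")
        path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# trimming

def trim_surface(mesh: TriangleSurfaceMesh, plane_normal, plane_offset: float) -> TriangleSurfaceMesh:
    """Clip a surface to the half-space ``n . x <= offset``.

    Faces crossing the plane are cut, introducing new vertices on the plane.
    When nothing lies beyond the plane the input is returned unchanged with
    a logged notice.  The per-vertex scalar channel, if any, is dropped
    (cut vertices have no well-defined value).
    """
    n = np.asarray(plane_normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("plane normal must be a nonzero vector")
    n = n / norm
    offset = float(plane_offset)
    signed = mesh.vertices @ n - offset
    if np.all(signed <= 1e-12):
        logger.info("trim plane does not cut the mesh; returning it unchanged")
        return replace(mesh)
    # slice_mesh_plane keeps the side its normal points to, so pass -n
    tm = mesh.to_trimesh()
    cut = trimesh.intersections.slice_mesh_plane(
        tm, plane_normal=-n, plane_origin=n * offset, cap=False)
    if cut is None or len(cut.faces) == 0:
        raise ValueError("trim plane removes the entire mesh")
    out = TriangleSurfaceMesh.from_trimesh(cut)
    # snap numerically-on-plane vertices exactly onto the plane
    d = out.vertices @ n - offset
    on_plane = np.abs(d) <= 1e-9
    out.vertices[on_plane] -= np.outer(d[on_plane], n)
    return out


def trim_above_plantar(mesh: TriangleSurfaceMesh, height: float = 65.0,
                       up=(0.0, 0.0, 1.0)) -> TriangleSurfaceMesh:
    """Trim everything more than ``height`` mm above the lowest plantar vertex.

    Mirrors how scanned foot surfaces are preprocessed: the scan is cut
    65 mm above the sole, measured along the gravity (+z) axis from the
    lowest vertex.
    """
    up = np.asarray(up, dtype=np.float64)
    up = up / np.linalg.norm(up)
    lowest = float((mesh.vertices @ up).min())
    return trim_surface(mesh, up, lowest + float(height))
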
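"""Triangulated surface meshes: container, PLY/VTK I/O and validation.

Vertices are in millimetres; faces are 0-based vertex-index triples oriented
by the right-hand rule on (v0, v1, v2).  PLY (ASCII and binary
little-endian) is handled through :mod:`trimesh`; the legacy ASCII VTK
POLYDATA format is read and written directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "MeshError",
    "MeshFormatError",
    "MeshIndexError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "ValidationReport",
]


class MeshError(Exception):
    """Base class for mesh failures."""


class MeshFormatError(MeshError):
    """File does not parse as an indexed triangle set."""


class MeshIndexError(MeshError):
    """A face refers to a vertex index outside [0, n_vertices) or repeats one."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface: the unit of population data.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of vertex indices, consistently oriented.
    name : optional label carried through pipelines.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError(f"faces must be (m, 3) triangles, got {self.faces.shape}")
        if len(self.vertices) < 3 or len(self.faces) < 1:
            raise MeshFormatError(
                f"need >= 3 vertices and >= 1 face, got {len(self.vertices)}/{len(self.faces)}"
            )
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshIndexError(
                f"face index out of range [0, {len(self.vertices)}): "
                f"min {self.faces.min()}, max {self.faces.max()}"
            )
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshIndexError("a face repeats a vertex index (degenerate topology)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new vertex positions."""
        return TriangleMesh(np.asarray(vertices, dtype=float), self.faces.copy(), self.name)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)


def _infer_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        return "ply"
    if ext == ".vtk":
        return "vtk"
    raise MeshFormatError(f"cannot infer mesh format from extension {ext!r}")


def _read_vtk(path: str) -> TriangleMesh:
    with open(path) as fh:
        tokens: list[str] = []
        for i, line in enumerate(fh):
            if i == 2 and line.strip().upper() != "ASCII":
                raise MeshFormatError("only ASCII legacy VTK is supported")
            if i < 4:
                continue  # header, description, ASCII, DATASET
            tokens.extend(line.split())
    it = iter(tokens)

    def expect(word: str) -> None:
        tok = next(it, None)
        if tok is None or tok.upper() != word:
            raise MeshFormatError(f"expected {word!r} in VTK file, got {tok!r}")

    expect("POINTS")
    n = int(next(it))
    next(it)  # dtype keyword
    verts = np.array([float(next(it)) for _ in range(3 * n)]).reshape(n, 3)
    expect("POLYGONS")
    m = int(next(it))
    int(next(it))  # total size
    faces = np.empty((m, 3), dtype=np.int64)
    for j in range(m):
        k = int(next(it))
        if k != 3:
            raise MeshFormatError(f"non-triangle cell with {k} vertices at polygon {j}")
        faces[j] = [int(next(it)) for _ in range(3)]
    return TriangleMesh(verts, faces, name=os.path.splitext(os.path.basename(path))[0])


def _write_vtk(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{mesh.name or 'diffcentroid mesh'}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str, format: str = "auto") -> TriangleMesh:
    """Read a triangulated surface from PLY or legacy ASCII VTK polydata."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "ply":
        try:
            tm = trimesh.load(path, file_type="ply", process=False)
        except Exception as exc:  # trimesh raises various types
            raise MeshFormatError(f"failed to parse PLY {path}: {exc}") from exc
        faces = np.asarray(tm.faces)
        if faces.size == 0 or faces.shape[1] != 3:
            raise MeshFormatError(f"{path} does not contain triangle faces")
        return TriangleMesh(
            np.asarray(tm.vertices, dtype=float),
            faces,
            name=os.path.splitext(os.path.basename(path))[0],
        )
    raise MeshFormatError(f"unknown format {fmt!r}")


def write_mesh(mesh: TriangleMesh, path: str, format: str = "auto") -> str:
    """Write a mesh; returns the path.  PLY is written as ASCII."""
    fmt = _infer_format(path, format)
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "ply":
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(path, file_type="ply", encoding="ascii")
    else:
        raise MeshFormatError(f"unknown format {fmt!r}")
    return path


@dataclass
class ValidationReport:
    """Reporting-only mesh diagnostics; never mutates the mesh."""

    face_areas: np.ndarray
    small_faces: np.ndarray  # indices of faces with area < min_area
    duplicate_vertices: list[tuple[int, int]]
    closed: bool
    consistently_oriented: bool

    @property
    def ok(self) -> bool:
        return (
            len(self.small_faces) == 0
            and not self.duplicate_vertices
            and self.closed
            and self.consistently_oriented
        )


def validate_mesh(mesh: TriangleMesh, min_area: float = 1e-10) -> ValidationReport:
    """Flag near-zero-area faces, duplicate vertices, openness and orientation.

    A mesh is closed when every undirected edge is shared by exactly two
    faces; a closed mesh is consistently oriented when every such edge is
    traversed once in each direction.
    """
    areas = mesh.face_areas()
    small = np.nonzero(areas < min_area)[0]

    order = np.lexsort(mesh.vertices.T)
    sv = mesh.vertices[order]
    dup_mask = np.all(np.isclose(sv[1:], sv[:-1], rtol=0, atol=0), axis=1)
    duplicates = [(int(order[i]), int(order[i + 1])) for i in np.nonzero(dup_mask)[0]]

    directed: dict[tuple[int, int], int] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
    undirected: dict[tuple[int, int], int] = {}
    for (a, b), c in directed.items():
        key = (a, b) if a < b else (b, a)
        undirected[key] = undirected.get(key, 0) + c
    closed = all(c == 2 for c in undirected.values())
    oriented = all(c == 1 for c in directed.values()) and (
        not closed or all(directed.get((b, a), 0) == 1 for (a, b) in directed)
    )
    return ValidationReport(
        face_areas=areas,
        small_faces=small,
        duplicate_vertices=duplicates,
        closed=closed,
        consistently_oriented=oriented,
    )
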
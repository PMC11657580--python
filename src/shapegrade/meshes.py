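"""Triangle-mesh data model, file I/O and elementary geometric queries.

Meshes are kept deliberately minimal: a vertex array, a face array and a bit
of subject metadata. All indices are 0-based internally; on-disk 1-based
conventions (OBJ) are handled by the I/O layer. Non-closed meshes are
accepted with a warning -- the downstream spectral machinery does not require
closedness -- but their genus is reported as undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh


class MeshError(ValueError):
    """Base class for mesh I/O and validation failures."""


class MeshFormatError(MeshError):
    """A mesh file could not be parsed in the requested format."""


class MeshValidationError(MeshError):
    """A mesh violates a structural invariant (degenerate or non-manifold)."""


_SIDES = ("left", "right", "none")
_FORMATS = ("off", "ply", "obj")


@dataclass
class TriangleMesh:
    """A triangle surface mesh (one anatomical structure of one subject).

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions. Units are opaque metadata; nothing is rescaled.
    faces : (F, 3) int array
        Counterclockwise vertex triples, 0-based.
    subject_id : str
        Identifier of the subject the mesh belongs to.
    side : {"left", "right", "none"}
        Laterality of the structure.
    """

    vertices: np.ndarray
    faces: np.ndarray
    subject_id: str = ""
    side: str = "none"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) int array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def is_closed(self) -> bool:
        """True iff every undirected edge borders exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def genus(self) -> int | None:
        """Genus from the Euler characteristic; None for non-closed meshes."""
        if not self.is_closed():
            return None
        chi = self.euler_characteristic()
        if chi % 2 != 0:
            raise MeshValidationError(f"odd Euler characteristic {chi}")
        return (2 - chi) // 2

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            self.subject_id, self.side, dict(self.metadata))


def validate_mesh(mesh: TriangleMesh) -> None:
    """Check structural invariants; raise :class:`MeshValidationError`.

    Checks: valid face indices, no degenerate (repeated-vertex) faces, and
    edge-manifoldness (each undirected edge borders at most two faces).
    Emits a warning for non-closed meshes instead of failing.
    """
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise MeshValidationError("empty mesh (no vertices or faces)")
    f = mesh.faces
    if f.min() < 0 or f.max() >= mesh.n_vertices:
        raise MeshValidationError(
            f"face index out of range (V={mesh.n_vertices})")
    degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    if degen.any():
        raise MeshValidationError(
            f"degenerate faces (repeated vertex): {np.flatnonzero(degen).tolist()}")
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    bad = uniq[counts > 2]
    if len(bad):
        raise MeshValidationError(
            f"non-manifold edges (more than 2 incident faces): {bad.tolist()}")
    if not mesh.is_closed():
        warnings.warn(f"mesh {mesh.subject_id!r} is not closed; "
                      "genus is undefined", stacklevel=2)


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise MeshFormatError(f"unsupported format {fmt!r}")
        return fmt
    ext = path.suffix.lower().lstrip(".")
    if ext not in _FORMATS:
        raise MeshFormatError(f"cannot infer mesh format from {path.name!r}")
    return ext


def read_mesh(path, format: str = "auto", subject_id: str = "",
              side: str = "none", validate: bool = True) -> TriangleMesh:
    """Read a triangle mesh from OFF / PLY (ascii or binary) / OBJ.

    Vertex order is preserved exactly as stored in the file.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    try:
        raw = _trimesh.load(str(path), file_type=fmt, process=False,
                            maintain_order=True, force="mesh")
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise MeshFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if raw.vertices is None or len(raw.vertices) == 0:
        raise MeshFormatError(f"{path}: no vertices parsed")
    mesh = TriangleMesh(np.asarray(raw.vertices), np.asarray(raw.faces),
                        subject_id=subject_id or path.stem, side=side)
    if validate:
        validate_mesh(mesh)
    return mesh


def write_mesh(mesh: TriangleMesh, path, format: str = "auto") -> None:
    """Write a mesh to disk; round-trips vertices to printed precision and
    the face list exactly."""
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise MeshError("refusing to write an empty mesh")
    path = Path(path)
    fmt = _infer_format(path, format)
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                          process=False)
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise MeshError(f"cannot write {path}: {exc}") from exc


def bounding_box_diagonal(mesh: TriangleMesh) -> float:
    """Length ``l`` of the axis-aligned bounding-box diagonal.

    This is the scale reference used to express the metric blending weight
    as ``omega = alpha * l**2``.
    """
    if mesh.n_vertices == 0:
        raise MeshError("empty mesh has no bounding box")
    span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    return float(np.linalg.norm(span))
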
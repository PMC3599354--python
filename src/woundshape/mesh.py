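"""Triangle-mesh data model, OBJ/PLY readers and writers, unit-square normalization.

A lesion patch is a single open triangle mesh: a centrally located surface
feature (the wound relief) surrounded by flat material.  Before any shape
descriptor is computed the patch is rescaled to fit into a unit square so
that classification is independent of physical lesion size; all curvature
thresholds downstream are expressed in this normalized frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: tolerance (in raw input units) under which two vertices are merged on read
DEDUP_TOL = 1e-9


class MeshError(Exception):
    """Base class for mesh-layer failures."""


class MeshFormatError(MeshError):
    """File could not be parsed as the declared format."""


class DegenerateMeshError(MeshError):
    """Mesh has too little geometry to be a valid lesion patch."""


@dataclass
class TriangleMesh:
    """A lesion patch: vertex coordinates plus triangle connectivity.

    Coordinates are in millimetres while ``frame_tag == "raw"`` and
    dimensionless after unit-square normalization
    (``frame_tag == "normalized"``).
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64, 0-based
    frame_tag: str = "raw"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if self.frame_tag not in ("raw", "normalized"):
            raise MeshError(f"unknown frame_tag {self.frame_tag!r}")
        if len(self.vertices) < 4:
            raise DegenerateMeshError("mesh needs at least 4 vertices")
        if len(self.faces) < 2:
            raise DegenerateMeshError("mesh needs at least 2 faces")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinate")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshError("face references a vertex index out of range")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise MeshError("face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.frame_tag)


@dataclass
class NormalizationRecord:
    """Transform applied by :func:`normalize_to_unit_square`.

    The forward map is ``(v + translation) * scale_factor``; inverting it
    recovers the raw coordinates.
    """

    scale_factor: float
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def invert(self, vertices: np.ndarray) -> np.ndarray:
        return vertices / self.scale_factor - self.translation


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FRAME_COMMENT = "woundshape frame=normalized"


def _scan_frame_tag(path: Path) -> str:
    """Look for the frame-tag sidecar comment in the (ASCII) file header."""
    try:
        head = path.open("rb").read(4096).decode("ascii", errors="ignore")
    except OSError:
        return "raw"
    return "normalized" if _FRAME_COMMENT in head else "raw"


def _clean(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge duplicate vertices (DEDUP_TOL) and drop degenerate faces."""
    key = np.round(vertices / DEDUP_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    n_dup = len(vertices) - len(first)
    # keep original ordering of the first occurrence of each vertex
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = vertices[np.sort(first)]
    faces = rank[inverse][faces]
    repeat = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    area2 = np.linalg.norm(np.cross(a, b), axis=1)
    degenerate = repeat | (area2 <= 0.0)
    if n_dup or degenerate.any():
        log.info(
            "mesh cleaning: merged %d duplicate vertices, dropped %d degenerate faces",
            n_dup,
            int(degenerate.sum()),
        )
    return vertices, faces[~degenerate]


def read_mesh(path: str | Path, fmt: str = "auto") -> TriangleMesh:
    """Read an OBJ or PLY triangle mesh.

    Duplicate vertices within ``DEDUP_TOL`` are merged and zero-area faces
    dropped (counted in the log).  The frame tag round-trips through a header
    comment written by :func:`write_mesh`.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("obj", "ply"):
        raise MeshFormatError(f"unsupported format {fmt!r}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        vertices = np.asarray(loaded.vertices, dtype=np.float64)
        faces = np.asarray(loaded.faces, dtype=np.int64)
    except Exception as exc:  # trimesh raises a zoo of types
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise MeshFormatError(f"{path}: face references vertex index out of range")
    vertices, faces = _clean(vertices, faces)
    if len(vertices) < 4 or len(faces) < 2:
        raise DegenerateMeshError(f"{path}: fewer than 4 vertices / 2 faces after cleaning")
    return TriangleMesh(vertices, faces, frame_tag=_scan_frame_tag(path))


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str = "auto") -> Path:
    """Write ``mesh`` as ASCII OBJ or PLY; the frame tag rides in a comment."""
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    comment = _FRAME_COMMENT if mesh.frame_tag == "normalized" else "woundshape frame=raw"
    try:
        if fmt == "obj":
            with path.open("w") as fh:
                fh.write(f"# {comment}\n")
                for v in mesh.vertices:
                    fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                for f in mesh.faces:  # OBJ is 1-based
                    fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        elif fmt == "ply":
            tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
            text = tm.export(file_type="ply", encoding="ascii").decode("ascii")
            lines = text.splitlines()
            lines.insert(2, f"comment {comment}")
            path.write_text("\n".join(lines) + "\n")
        else:
            raise MeshFormatError(f"unsupported format {fmt!r}")
    except OSError as exc:
        raise MeshError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_to_unit_square(mesh: TriangleMesh) -> tuple[TriangleMesh, NormalizationRecord]:
    """Center the patch on its centroid and scale it into the unit square.

    All three axes are scaled by the same factor, chosen so that the larger
    of the x- and y-extents becomes exactly 1.  Uniform scaling preserves all
    pairwise-distance ratios, so curvature structure survives (curvatures are
    simply divided by the scale factor), and the origin-centered concentric
    spheres used downstream are well defined.
    """
    if mesh.frame_tag != "raw":
        raise MeshError("normalize_to_unit_square expects a raw-frame mesh")
    centroid = mesh.vertices.mean(axis=0)
    shifted = mesh.vertices - centroid
    ext = shifted.max(axis=0) - shifted.min(axis=0)
    planar = max(ext[0], ext[1])
    if planar <= 0.0:
        raise DegenerateMeshError("zero planar extent: vertices collinear along z")
    scale = 1.0 / planar
    out = TriangleMesh(shifted * scale, mesh.faces.copy(), frame_tag="normalized")
    return out, NormalizationRecord(scale_factor=scale, translation=-centroid)
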
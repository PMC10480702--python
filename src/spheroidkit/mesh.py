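"""Triangle-mesh loading, cleaning and derived per-face quantities.

All downstream metrics consume :class:`TriangleMesh`, a thin immutable wrapper
around a cleaned ``trimesh.Trimesh``.  Coordinates are millimetres throughout;
:func:`load_mesh` rescales from other unit tags at read time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: scale factors into millimetres
_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3}

_SUPPORTED_SUFFIXES = {".ply", ".obj", ".stl"}


@dataclass(frozen=True)
class RepairLog:
    """Counts of repairs applied while cleaning a mesh."""

    merged_vertices: int = 0
    dropped_faces: int = 0
    normals_fixed: bool = False


@dataclass(frozen=True)
class TriangleMesh:
    """A cleaned triangle mesh with derived per-face quantities (units: mm).

    Faces index into ``vertices``; normals are consistently outward for
    watertight meshes.  Derived quantities are computed lazily and cached.
    """

    vertices: np.ndarray
    faces: np.ndarray
    units: str = "mm"
    repair_log: RepairLog = field(default_factory=RepairLog)
    source: str | None = None

    def __post_init__(self):
        v = np.ascontiguousarray(self.vertices, dtype=float)
        f = np.ascontiguousarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be triangles (m, 3)")
        if len(f) == 0:
            raise ValueError("empty mesh")
        if f.max() >= len(v):
            raise ValueError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- derived quantities -------------------------------------------------
    @cached_property
    def _tm(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @cached_property
    def face_areas(self) -> np.ndarray:
        return self._tm.area_faces

    @cached_property
    def face_normals(self) -> np.ndarray:
        return self._tm.face_normals

    @cached_property
    def face_centroids(self) -> np.ndarray:
        return self._tm.triangles_center

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @cached_property
    def watertight(self) -> bool:
        return bool(self._tm.is_watertight)

    @cached_property
    def volume(self) -> float | None:
        """Signed-tetrahedron (divergence theorem) volume; None if open."""
        if not self.watertight:
            return None
        return float(abs(self._tm.volume))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @cached_property
    def r_eq(self) -> float:
        """Equal-volume-sphere radius (mm); falls back to the equal-area
        radius sqrt(A / 4 pi) for non-watertight meshes."""
        if self.volume is not None:
            return float((3.0 * self.volume / (4.0 * np.pi)) ** (1.0 / 3.0))
        warnings.warn(
            "mesh is not watertight; r_eq falls back to equal-area radius",
            stacklevel=2,
        )
        return float(np.sqrt(self.total_area / (4.0 * np.pi)))

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, **kw) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), **kw)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "TriangleMesh":
        """Similarity-transformed copy (rotation rows applied as v @ R.T)."""
        v = self.vertices * scale
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces, units=self.units,
                            repair_log=self.repair_log, source=self.source)


def clean_mesh(tm: trimesh.Trimesh, source: str | None = None) -> TriangleMesh:
    """Merge duplicate vertices, drop zero-area faces, orient normals outward."""
    n_v0, n_f0 = len(tm.vertices), len(tm.faces)
    tm = tm.copy()
    tm.merge_vertices()
    merged = n_v0 - len(tm.vertices)
    areas = tm.area_faces
    keep = areas > max(areas.max(), 1e-300) * 1e-12
    dropped = int((~keep).sum())
    if dropped:
        tm.update_faces(keep)
    tm.remove_unreferenced_vertices()
    normals_fixed = False
    if tm.is_watertight:
        trimesh.repair.fix_normals(tm)
        if tm.volume < 0:
            tm.invert()
        normals_fixed = True
    if len(tm.faces) == 0:
        raise ValueError("mesh has no non-degenerate faces")
    if merged or dropped:
        log.info("cleaned mesh %s: merged %d vertices, dropped %d faces",
                 source or "<memory>", merged, dropped)
    return TriangleMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces),
        repair_log=RepairLog(merged, dropped, normals_fixed), source=source,
    )


def load_mesh(path: str | Path, units: str = "mm") -> TriangleMesh:
    """Read a PLY/OBJ/STL file and return a cleaned :class:`TriangleMesh`.

    Quad OBJ faces are fan-triangulated by the reader in deterministic vertex
    order.  ``units`` rescales coordinates to millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    if units not in _UNIT_SCALE:
        raise ValueError(f"unknown units {units!r}; choose from {sorted(_UNIT_SCALE)}")
    loaded = trimesh.load(path, force="mesh", process=False)
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise ValueError(f"{path} did not contain a triangulatable mesh")
    loaded.apply_scale(_UNIT_SCALE[units])
    return clean_mesh(loaded, source=str(path))


@dataclass(frozen=True)
class MeshSummary:
    n_vertices: int
    n_faces: int
    total_area: float  # mm^2
    volume: float | None  # mm^3, None when not watertight
    extents: tuple[float, float, float]  # mm, world AABB
    r_eq: float  # mm
    watertight: bool


def mesh_summary(mesh: TriangleMesh) -> MeshSummary:
    """Counts, area, volume, extents and the equal-volume-sphere radius."""
    ext = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    return MeshSummary(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        total_area=mesh.total_area,
        volume=mesh.volume,
        extents=tuple(float(e) for e in ext),
        r_eq=mesh.r_eq,
        watertight=mesh.watertight,
    )
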
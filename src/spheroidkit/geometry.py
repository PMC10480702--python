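"""Principal orientation, centre of mass and bounding-box dispersion.

The principal frame comes from the *surface tensor*: the area-weighted second
moment of the outward face normals.  Its eigenvectors give three orthogonal
symmetry planes that position the artefact before bounding-box and
spherical-harmonics analysis.  The CoM/CoBB separation, normalised by the
equal-volume-sphere radius, measures how evenly the surface is distributed:
it is zero for a perfect sphere and grows with one-sided protuberances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh

_DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class PrincipalFrame:
    """Right-handed orthonormal axes (rows) with descending eigenvalues."""

    axes: np.ndarray  # (3, 3), rows are unit vectors in world coordinates
    eigenvalues: np.ndarray  # (3,), descending, non-negative

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World points -> frame coordinates."""
        return np.asarray(points) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.axes


@dataclass(frozen=True)
class MassCenters:
    com: np.ndarray  # (3,), mm
    cobb: np.ndarray  # (3,), mm
    raw_distance: float  # mm
    normalized_distance: float  # raw / r_eq, dimensionless


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-magnitude component is positive; restore
    right-handedness (det +1) by flipping the last axis if needed."""
    axes = axes.copy()
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _align_subspace(basis: np.ndarray) -> np.ndarray:
    """Re-span a degenerate eigen-subspace (rows of `basis`) by directions as
    close to the world axes as possible (deterministic tie-break)."""
    k = basis.shape[0]
    proj = basis.T @ basis  # projector onto subspace (3, 3)
    # candidate directions: projections of world axes, largest norm first
    cand = proj.copy()
    norms = np.linalg.norm(cand, axis=1)
    order = np.argsort(-norms)
    out = []
    for idx in order:
        v = cand[idx].copy()
        for u in out:
            v -= (v @ u) * u
        n = np.linalg.norm(v)
        if n > 1e-9:
            out.append(v / n)
        if len(out) == k:
            break
    return np.array(out)


def surface_tensor(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted second-moment tensor of face normals, trace 1."""
    n = mesh.face_normals
    a = mesh.face_areas
    t = np.einsum("f,fi,fj->ij", a, n, n) / a.sum()
    return t


def principal_frame(mesh: TriangleMesh) -> PrincipalFrame:
    """Eigen-decomposition of the surface tensor with deterministic signs.

    Near-degenerate eigenvalue pairs (relative gap < 1e-6) are tie-broken by
    aligning the degenerate subspace with the world axes; a fully isotropic
    spectrum (e.g. a sphere) returns the world frame.
    """
    t = surface_tensor(mesh)
    evals, evecs = np.linalg.eigh(t)  # ascending
    evals = evals[::-1]
    axes = evecs.T[::-1]  # rows, descending eigenvalue order
    scale = max(evals[0], 1e-300)
    gap01 = (evals[0] - evals[1]) / scale
    gap12 = (evals[1] - evals[2]) / scale
    if gap01 < _DEGENERACY_TOL and gap12 < _DEGENERACY_TOL:
        axes = np.eye(3)
    elif gap01 < _DEGENERACY_TOL:
        axes[:2] = _align_subspace(axes[:2])
    elif gap12 < _DEGENERACY_TOL:
        axes[1:] = _align_subspace(axes[1:])
    axes = _fix_signs(axes)
    return PrincipalFrame(axes=axes, eigenvalues=np.clip(evals, 0.0, None))


def centre_of_mass(mesh: TriangleMesh, method: str = "area-weighted") -> np.ndarray:
    """Centre of mass of the surface (default) or the enclosed solid.

    ``area-weighted`` is the surface centroid sum(area_f * centroid_f) / A --
    the quantity the original measurement software reports.  ``volumetric``
    is the true solid centroid via the divergence theorem and requires a
    watertight mesh.
    """
    if method == "area-weighted":
        a = mesh.face_areas
        return np.asarray((a[:, None] * mesh.face_centroids).sum(axis=0) / a.sum())
    if method == "volumetric":
        if not mesh.watertight:
            raise ValueError("volumetric centre of mass requires a watertight mesh")
        return np.asarray(mesh._tm.center_mass, dtype=float)
    raise ValueError(f"unknown method {method!r}")


def mass_centers(
    mesh: TriangleMesh,
    frame: PrincipalFrame | None = None,
    world_aabb: bool = False,
    com_method: str = "area-weighted",
) -> MassCenters:
    """CoM, centre of the principal-frame bounding box, and their separation.

    The bounding box is axis-aligned in the principal frame (the object's
    "given orientation"); pass ``world_aabb=True`` for a world-axis box.
    ``normalized_distance`` divides by the equal-volume-sphere radius r_eq,
    making the value dimensionless and similarity-invariant.
    """
    if world_aabb:
        axes = np.eye(3)
    else:
        if frame is None:
            frame = principal_frame(mesh)
        axes = frame.axes
    coords = mesh.vertices @ axes.T
    mid = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    cobb = mid @ axes
    com = centre_of_mass(mesh, method=com_method)
    raw = float(np.linalg.norm(com - cobb))
    return MassCenters(
        com=com, cobb=cobb, raw_distance=raw,
        normalized_distance=raw / mesh.r_eq,
    )
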
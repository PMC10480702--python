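"""Edge angles between surfaces and primary-surface patch metrics.

The *angle between surfaces* measurement fits total-least-squares planes to
two point sets picked along an edge, trims the worst-fitting points once
(keeping the most regular portion of each surface) and reports the dihedral
angle measured through the material side: 180 degrees for a coplanar
continuation, 90 for perpendicular surfaces, approaching 0 for a fold-back.

A *primary surface* is a reserved large flat or concave facet used as the
striking platform for most removals.  Its area proportion of the total
surface is the reduction-intensity proxy: large early in reduction,
shrinking as flakes are struck from its perimeter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .mesh import TriangleMesh

__all__ = [
    "EdgeAngleMeasurement",
    "SurfacePatch",
    "fit_plane_tls",
    "angle_between_surfaces",
    "patch_metrics",
    "reduction_proxy",
    "score_primary_candidate",
    "load_annotation",
    "save_annotation",
]

TRIM_FLOOR = 0.6  # minimum inlier fraction after trimming


@dataclass(frozen=True)
class EdgeAngleMeasurement:
    points_a: np.ndarray
    points_b: np.ndarray
    normal_a: np.ndarray  # oriented away from the material
    normal_b: np.ndarray
    inlier_fraction_a: float
    inlier_fraction_b: float
    angle: float  # degrees in (0, 180]


@dataclass(frozen=True)
class SurfacePatch:
    """A labelled face-index set with optional filled metrics."""

    label: str
    face_indices: np.ndarray
    area_proportion: float | None = None
    planarity_rms: float | None = None  # mm
    signed_concavity: float | None = None  # + = concave toward the material
    platform_angle: float | None = None  # degrees
    gauss_deviation: float | None = None
    artifact_id: str | None = None

    def __post_init__(self):
        idx = np.unique(np.asarray(self.face_indices, dtype=np.int64))
        if idx.size == 0:
            raise ValueError("patch must contain at least one face")
        object.__setattr__(self, "face_indices", idx)


def fit_plane_tls(
    points: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted total-least-squares plane.

    Returns (unit normal, centroid, signed residuals).  The normal is the
    smallest principal direction of the weighted covariance; its sign is not
    meaningful until oriented by the caller.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu = w @ pts
    d = pts - mu
    cov = np.einsum("n,ni,nj->ij", w, d, d)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1e-300):
        raise ValueError("points are collinear; plane is undefined")
    n = evecs[:, 0]
    return n, mu, d @ n


def angle_between_surfaces(
    points_a: np.ndarray, points_b: np.ndarray, trim: float = 0.2
) -> EdgeAngleMeasurement:
    """Dihedral angle (degrees) between two planar point sets.

    Each set is fitted by a TLS plane; the worst ``trim`` fraction of points
    by absolute residual is dropped and the plane refitted once.  Normals are
    oriented away from the material (away from the midpoint between the two
    set centroids) and the returned angle is measured through the material:
    ``180 - angle(normal_a, normal_b)``.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")

    def fit_trimmed(pts):
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 4:
            raise ValueError("need at least 4 points per surface")
        n, mu, res = fit_plane_tls(pts)
        n_drop = int(np.floor(trim * len(pts)))
        keep_n = len(pts) - n_drop
        if keep_n < max(4, int(np.ceil(TRIM_FLOOR * len(pts)))):
            keep_n = max(4, int(np.ceil(TRIM_FLOOR * len(pts))))
        order = np.argsort(np.abs(res), kind="stable")
        kept = pts[np.sort(order[:keep_n])]
        n, mu, _ = fit_plane_tls(kept)
        return n, mu, keep_n / len(pts)

    n_a, c_a, in_a = fit_trimmed(points_a)
    n_b, c_b, in_b = fit_trimmed(points_b)

    scale = max(np.linalg.norm(c_a - c_b), 1.0)
    mid = 0.5 * (c_a + c_b)
    s_a = n_a @ (c_a - mid)
    s_b = n_b @ (c_b - mid)
    tol = 1e-9 * scale
    if abs(s_a) > tol and s_a < 0:
        n_a = -n_a
    if abs(s_b) > tol and s_b < 0:
        n_b = -n_b
    if abs(s_a) <= tol and abs(s_b) <= tol:
        # coplanar continuation: align normals so the angle reads 180
        if n_a @ n_b < 0:
            n_b = -n_b
    cosang = float(np.clip(n_a @ n_b, -1.0, 1.0))
    angle = 180.0 - np.degrees(np.arccos(cosang))
    return EdgeAngleMeasurement(
        points_a=np.asarray(points_a, float), points_b=np.asarray(points_b, float),
        normal_a=n_a, normal_b=n_b,
        inlier_fraction_a=in_a, inlier_fraction_b=in_b,
        angle=float(angle),
    )


def _boundary_edges(mesh: TriangleMesh, in_patch: np.ndarray) -> np.ndarray:
    """(n, 2) array of [patch_face, exterior_face] pairs across the boundary."""
    tm = mesh._tm
    adj = tm.face_adjacency  # (m, 2) face index pairs sharing an edge
    a_in = in_patch[adj[:, 0]]
    b_in = in_patch[adj[:, 1]]
    cross = a_in != b_in
    pairs = adj[cross]
    flip = ~in_patch[pairs[:, 0]]
    pairs[flip] = pairs[flip][:, ::-1]
    return pairs


def _patch_platform_angle(mesh: TriangleMesh, in_patch: np.ndarray) -> float:
    """Edge-length-weighted mean dihedral between the patch and its exterior.

    Per boundary edge, the angle between the adjacent patch face and exterior
    face planes follows the same through-the-material convention as
    :func:`angle_between_surfaces` (flat continuation = 180 degrees).
    """
    tm = mesh._tm
    adj = tm.face_adjacency
    a_in = in_patch[adj[:, 0]]
    b_in = in_patch[adj[:, 1]]
    cross = a_in != b_in
    if not cross.any():
        raise ValueError("patch covers the whole surface; platform angle undefined")
    pairs = adj[cross]
    edges = tm.face_adjacency_edges[cross]
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    n1 = mesh.face_normals[pairs[:, 0]]
    n2 = mesh.face_normals[pairs[:, 1]]
    cosang = np.clip(np.einsum("ij,ij->i", n1, n2), -1.0, 1.0)
    angles = 180.0 - np.degrees(np.arccos(cosang))
    return float(np.average(angles, weights=lengths))


def patch_metrics(
    mesh: TriangleMesh,
    patch: SurfacePatch,
    gauss=None,
) -> SurfacePatch:
    """Fill a patch's area proportion, planarity, concavity and platform angle.

    ``signed_concavity`` is the mean signed depth of the patch vertices below
    the TLS plane of the patch's *boundary ring* (inward, toward the centre
    of mass, positive), normalised by the boundary ring diameter; it is 0 for
    a planar facet, positive for a dish, negative for a dome.  When a
    :class:`~spheroidkit.spharm.GaussMap` is passed, the patch's mean Gauss
    deviation is filled as well.
    """
    from .geometry import centre_of_mass
    from .spharm import patch_gauss_deviation

    idx = patch.face_indices
    if idx.max() >= mesh.n_faces:
        raise ValueError("patch face index exceeds mesh face count")
    area_proportion = float(mesh.face_areas[idx].sum() / mesh.total_area)

    in_patch = np.zeros(mesh.n_faces, dtype=bool)
    in_patch[idx] = True
    vids = np.unique(mesh.faces[idx])
    pverts = mesh.vertices[vids]

    n, mu, res = fit_plane_tls(pverts)
    planarity_rms = float(np.sqrt(np.mean(res**2)))

    com = centre_of_mass(mesh)
    if n @ (mu - com) < 0:
        n = -n

    signed_concavity = None
    platform_angle = None
    whole = bool(in_patch.all())
    if whole:
        raise ValueError(
            "patch covers the whole surface; platform angle undefined"
        )
    if not whole:
        pairs = _boundary_edges(mesh, in_patch)
        bvids = np.unique(
            np.concatenate([mesh.faces[pairs[:, 0]], mesh.faces[pairs[:, 1]]])
        )
        bvids = np.intersect1d(bvids, vids)
        ring = mesh.vertices[bvids]
        if len(ring) >= 3:
            try:
                nb, cb, _ = fit_plane_tls(ring)
            except ValueError:
                nb = None
            if nb is not None:
                if nb @ (cb - com) < 0:
                    nb = -nb
                depth = (cb - pverts) @ nb  # + below the rim plane (inward)
                d = ring - ring.mean(axis=0)
                diameter = 2.0 * float(np.linalg.norm(d, axis=1).max())
                if diameter > 0:
                    signed_concavity = float(depth.mean() / diameter)
        platform_angle = _patch_platform_angle(mesh, in_patch)

    gauss_dev = patch.gauss_deviation
    if gauss is not None:
        gauss_dev = patch_gauss_deviation(gauss, idx, mesh)

    return replace(
        patch,
        area_proportion=area_proportion,
        planarity_rms=planarity_rms,
        signed_concavity=signed_concavity,
        platform_angle=platform_angle,
        gauss_deviation=gauss_dev,
    )


def reduction_proxy(patch: SurfacePatch) -> float:
    """Reduction-intensity proxy: the primary surface's area proportion.

    Smaller proportion = more reduced; ordering artefacts by descending
    proportion orders them along the reduction sequence.
    """
    if patch.area_proportion is None:
        raise ValueError(
            "patch metrics not filled; run patch_metrics before reduction_proxy"
        )
    return float(patch.area_proportion)


def score_primary_candidate(patch: SurfacePatch) -> float:
    """Heuristic primary-surface score (higher = more primary-like).

    Combines area proportion, planarity (relative to patch scale), concavity
    and Gauss deviation with admittedly arbitrary equal weights.  Offered as
    a screening aid only; identification remains an expert annotation task
    and this score is never applied automatically.
    """
    if patch.area_proportion is None:
        raise ValueError("patch metrics not filled")
    score = patch.area_proportion
    if patch.signed_concavity is not None:
        score += max(patch.signed_concavity, 0.0)
    if patch.gauss_deviation is not None:
        score += patch.gauss_deviation
    return float(score)


def load_annotation(path: str | Path) -> SurfacePatch:
    """Read a JSON patch annotation {artifact_id, label, face_indices}."""
    with open(path) as fh:
        data = json.load(fh)
    return SurfacePatch(
        label=data.get("label", "primary"),
        face_indices=np.asarray(data["face_indices"], dtype=np.int64),
        artifact_id=data.get("artifact_id"),
    )


def save_annotation(patch: SurfacePatch, path: str | Path) -> None:
    payload = {
        "artifact_id": patch.artifact_id,
        "label": patch.label,
        "face_indices": patch.face_indices.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
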
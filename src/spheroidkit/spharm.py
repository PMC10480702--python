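"""Radial spherical parametrization, sphericalness and Gauss deviation maps.

An artefact that is star-shaped with respect to its centre of mass can be
written as three functions on the unit sphere: the Cartesian coordinates
x(theta, phi), y(theta, phi), z(theta, phi) of the surface point hit by the
ray in direction (theta, phi).  Expanding each coordinate function in real
orthonormal spherical harmonics concentrates a perfect sphere's energy
entirely in degree l = 1, split evenly across the three functions.  The
*sphericalness deviation* scores each coordinate function's normalised
degree-1 energy against the ideal value 1/3 and sums the absolute
differences: 0 for a perfect sphere, growing with faceting and topography.

The Gauss map is the companion visual diagnostic: a 100 x 100 grid over
(theta, phi) whose cells hold the relative deviation |r - r_mean| / r_mean
from the best-fit sphere, localising *where* an artefact departs from
sphericity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import cKDTree

from . import harmonics
from .geometry import PrincipalFrame, centre_of_mass
from .mesh import TriangleMesh

__all__ = [
    "RadialSamples",
    "SpharmExpansion",
    "GaussMap",
    "NotStarShapedError",
    "radial_parametrization",
    "spharm_expand",
    "spharm_reconstruct",
    "reconstruction_rms_error",
    "gauss_map",
    "patch_gauss_deviation",
]

DEFAULT_GRID = 256
DEFAULT_LMAX = 20
GAUSS_SHAPE = (100, 100)


class NotStarShapedError(ValueError):
    """A ray from the centre of mass crossed the surface more than once."""

    def __init__(self, theta: float, phi: float, n_hits: int):
        self.theta, self.phi, self.n_hits = theta, phi, n_hits
        super().__init__(
            f"mesh is not star-shaped about its centre of mass: ray at "
            f"theta={theta:.4f}, phi={phi:.4f} rad crosses the surface "
            f"{n_hits} times"
        )


@dataclass(frozen=True)
class RadialSamples:
    """r(theta, phi) on a midpoint-equiangular grid, in frame coordinates."""

    r: np.ndarray  # (n_lat, n_lon), mm
    theta: np.ndarray  # (n_lat,)
    phi: np.ndarray  # (n_lon,)
    origin: np.ndarray  # (3,), world coordinates of the ray origin (CoM)
    axes: np.ndarray  # (3, 3) rows: frame axes in world coordinates

    @cached_property
    def directions(self) -> np.ndarray:
        """Unit grid directions in frame coordinates, (n_lat, n_lon, 3)."""
        t, p = np.meshgrid(self.theta, self.phi, indexing="ij")
        return np.stack(
            [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=-1
        )

    @cached_property
    def points(self) -> np.ndarray:
        """Sampled surface points in frame coordinates, (n_lat, n_lon, 3)."""
        return self.r[..., None] * self.directions

    @cached_property
    def solid_angle_weights(self) -> np.ndarray:
        """Per-row quadrature weights (already include d phi)."""
        return harmonics.quadrature_weights(len(self.theta), len(self.phi))

    @property
    def mean_radius(self) -> float:
        """Solid-angle-weighted mean radius = best-fit sphere radius (mm)."""
        w = np.broadcast_to(self.solid_angle_weights[:, None], self.r.shape)
        return float((w * self.r).sum() / w.sum())


def _moller_trumbore(dirs: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Ray-triangle distances for rays from the origin.

    dirs: (n, 3); tri: (n, k, 3, 3).  Returns t (n, k) with NaN for misses.
    """
    eps = 1e-12
    v0, v1, v2 = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    e1, e2 = v1 - v0, v2 - v0
    d = dirs[:, None, :]
    p = np.cross(d, e2)
    det = np.einsum("nki,nki->nk", e1, p)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = -v0
    u = np.einsum("nki,nki->nk", tvec, p) * inv
    q = np.cross(tvec, e1)
    v = np.einsum("nki,nki->nk", np.broadcast_to(d, e1.shape), q) * inv
    t = np.einsum("nki,nki->nk", e2, q) * inv
    geom_eps = 1e-9
    hit = ok & (u >= -geom_eps) & (v >= -geom_eps) & (u + v <= 1 + geom_eps) & (t > eps)
    return np.where(hit, t, np.nan)


def _cast_rays(dirs, tri_all, tree, k, chunk=16384):
    """Radial distance and distinct-hit count per unit direction."""
    n = len(dirs)
    r = np.full(n, np.nan)
    hits = np.zeros(n, dtype=int)
    for lo in range(0, n, chunk):
        d = dirs[lo:lo + chunk]
        _, idx = tree.query(d, k=k)
        t = _moller_trumbore(d, tri_all[idx])
        t_sorted = np.sort(t, axis=1)  # NaNs last
        first = t_sorted[:, 0]
        ref = np.where(np.isfinite(first), first, 1.0)
        # count distinct crossings: consecutive sorted hits further apart
        # than 1e-6 (relative) belong to different surface crossings
        extra = np.zeros(len(d), dtype=int)
        for col in range(1, t_sorted.shape[1]):
            prev = t_sorted[:, col - 1]
            cur = t_sorted[:, col]
            extra += (np.isfinite(cur) & (cur - prev > 1e-6 * ref)).astype(int)
        hits[lo:lo + chunk] = np.isfinite(first).astype(int) + extra
        r[lo:lo + chunk] = first
    return r, hits


def radial_parametrization(
    mesh: TriangleMesh,
    grid_resolution: int = DEFAULT_GRID,
    frame: PrincipalFrame | None = None,
    origin: np.ndarray | None = None,
) -> RadialSamples:
    """Sample r(theta, phi) by ray casting from the centre of mass.

    The mesh must be star-shaped about the origin: each grid ray must cross
    the surface exactly once (checked against candidate faces near the ray
    direction; a second distinct crossing raises
    :class:`NotStarShapedError`).  Rays that graze an edge or vertex exactly
    are retried with a slightly perturbed direction.

    When ``frame`` is given, directions (and the returned samples) live in
    that principal frame, which canonicalises orientation.
    """
    if grid_resolution < 4:
        raise ValueError("grid_resolution must be >= 4")
    origin = centre_of_mass(mesh) if origin is None else np.asarray(origin, float)
    axes = np.eye(3) if frame is None else frame.axes

    verts = (mesh.vertices - origin) @ axes.T
    tri = verts[mesh.faces]  # (m, 3, 3)
    centroids = tri.mean(axis=1)
    cdirs = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    tree = cKDTree(cdirs)

    n_lat = n_lon = grid_resolution
    theta, phi = harmonics.grid_angles(n_lat, n_lon)
    t, p = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=-1
    ).reshape(-1, 3)

    k = min(24, len(mesh.faces))
    r, hits = _cast_rays(dirs, tri, tree, k)

    missed = ~np.isfinite(r)
    if missed.any():  # widen candidate set, then perturb grazing rays
        k2 = min(96, len(mesh.faces))
        r2, h2 = _cast_rays(dirs[missed], tri, tree, k2)
        r[missed], hits[missed] = r2, h2
        missed = ~np.isfinite(r)
    if missed.any():
        rng = np.random.default_rng(0)
        d = dirs[missed] + rng.normal(scale=1e-9, size=(missed.sum(), 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r2, h2 = _cast_rays(d, tri, tree, min(96, len(mesh.faces)))
        r[missed], hits[missed] = r2, h2
        missed = ~np.isfinite(r)
    if missed.any():
        # exact fallback: test the remaining rays against every face
        for i in np.flatnonzero(missed):
            t_all = _moller_trumbore(dirs[i][None], tri[None]).ravel()
            ts = np.sort(t_all[np.isfinite(t_all)])
            if ts.size:
                r[i] = ts[0]
                hits[i] = 1 + int(np.sum(np.diff(ts) > 1e-6 * ts[0]))
    if not np.isfinite(r).all():
        i = int(np.flatnonzero(~np.isfinite(r))[0])
        raise NotStarShapedError(t.ravel()[i], p.ravel()[i], 0)
    multi = hits > 1
    if multi.any():
        i = int(np.flatnonzero(multi)[0])
        raise NotStarShapedError(t.ravel()[i], p.ravel()[i], int(hits[i]))

    return RadialSamples(
        r=r.reshape(n_lat, n_lon), theta=theta, phi=phi,
        origin=origin, axes=axes,
    )


@dataclass(frozen=True)
class SpharmExpansion:
    """Per-axis real spherical-harmonics coefficients and sphericalness.

    ``coeffs[i]`` holds the (2, lmax+1, lmax+1) cosine/sine coefficient
    arrays of coordinate function i (x, y, z in frame coordinates).
    ``first_three[i]`` is coordinate function i's degree-1 band energy as a
    fraction of its total energy, scaled so a perfect sphere gives exactly
    1/3 per function; ``sphericalness_deviation`` sums |first_three - 1/3|.
    """

    lmax: int
    coeffs: np.ndarray  # (3, 2, lmax+1, lmax+1)
    band_energies: np.ndarray  # (lmax+1, 3)
    first_three: np.ndarray  # (3,)
    sphericalness_deviation: float
    grid_resolution: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def coefficient_norm(self) -> float:
        """Euclidean norm of the raw coefficient vector (all axes/degrees)."""
        return float(np.sqrt((self.coeffs**2).sum()))


def spharm_expand(samples: RadialSamples, lmax: int = DEFAULT_LMAX) -> SpharmExpansion:
    """Expand the three coordinate functions and score sphericalness."""
    n_lat = len(samples.theta)
    if n_lat < 2 * (lmax + 1):
        raise ValueError(
            f"grid resolution {n_lat} too small for lmax={lmax}; "
            f"need >= {2 * (lmax + 1)}"
        )
    f = samples.points  # (n_lat, n_lon, 3), already centred at CoM
    coeffs = np.empty((3, 2, lmax + 1, lmax + 1))
    for i in range(3):
        coeffs[i] = harmonics.analyze_grid(f[..., i], lmax)
    energies = np.stack(
        [harmonics.band_energies(coeffs[i]) for i in range(3)], axis=1
    )  # (lmax+1, 3)
    total = energies.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("degenerate parametrization: zero-energy coordinate")
    first_three = energies[1] / (3.0 * total)
    deviation = float(np.abs(first_three - 1.0 / 3.0).sum())
    return SpharmExpansion(
        lmax=lmax, coeffs=coeffs, band_energies=energies,
        first_three=first_three, sphericalness_deviation=deviation,
        grid_resolution=n_lat, origin=samples.origin, axes=samples.axes,
    )


def _grid_mesh(points: np.ndarray) -> TriangleMesh:
    """Close a (n_lat, n_lon, 3) point grid into a watertight UV mesh."""
    n_lat, n_lon, _ = points.shape
    verts = points.reshape(-1, 3)
    north = points[0].mean(axis=0)
    south = points[-1].mean(axis=0)
    verts = np.vstack([verts, north[None], south[None]])
    i_n, i_s = len(verts) - 2, len(verts) - 1

    def vid(i, j):
        return i * n_lon + (j % n_lon)

    faces = []
    for i in range(n_lat - 1):
        for j in range(n_lon):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append((a, c, b))
            faces.append((b, c, d))
    for j in range(n_lon):
        faces.append((i_n, vid(0, j), vid(0, j + 1)))
        faces.append((i_s, vid(n_lat - 1, j + 1), vid(n_lat - 1, j)))
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def spharm_reconstruct(
    expansion: SpharmExpansion, l: int, grid_resolution: int | None = None
) -> TriangleMesh:
    """Synthesise the shape truncated at degree l as a triangle mesh."""
    if l > expansion.lmax:
        raise ValueError(f"l={l} exceeds expansion lmax={expansion.lmax}")
    n = grid_resolution or expansion.grid_resolution
    pts = np.stack(
        [harmonics.synthesize_grid(expansion.coeffs[i], n, n, lmax=l)
         for i in range(3)],
        axis=-1,
    )
    return _grid_mesh(pts)


def reconstruction_rms_error(
    expansion: SpharmExpansion, samples: RadialSamples, l: int
) -> float:
    """RMS distance between samples and the degree-l truncated synthesis."""
    if l > expansion.lmax:
        raise ValueError(f"l={l} exceeds expansion lmax={expansion.lmax}")
    n_lat, n_lon = samples.r.shape
    rec = np.stack(
        [harmonics.synthesize_grid(expansion.coeffs[i], n_lat, n_lon, lmax=l)
         for i in range(3)],
        axis=-1,
    )
    d2 = ((rec - samples.points) ** 2).sum(axis=-1)
    w = np.broadcast_to(samples.solid_angle_weights[:, None], d2.shape)
    return float(np.sqrt((w * d2).sum() / w.sum()))


@dataclass(frozen=True)
class GaussMap:
    """Binned relative deviation from the best-fit sphere per direction."""

    grid: np.ndarray  # (n_theta, n_phi), >= 0
    theta_edges: np.ndarray
    phi_edges: np.ndarray
    mean_radius: float  # mm
    fill_policy: str  # how empty cells were filled
    origin: np.ndarray
    axes: np.ndarray

    @property
    def mean_deviation(self) -> float:
        """Solid-angle-weighted mean cell deviation."""
        w = np.diff(-np.cos(self.theta_edges))[:, None] * np.diff(self.phi_edges)
        return float((w * self.grid).sum() / w.sum())


def gauss_map(samples: RadialSamples, shape: tuple[int, int] = GAUSS_SHAPE) -> GaussMap:
    """Bin |r - r_mean| / r_mean onto a (theta, phi) grid by cell mean.

    Empty cells (possible only when the sampling grid is coarser than the
    map) are filled from the nearest non-empty cell.
    """
    n_t, n_p = shape
    r_bar = samples.mean_radius
    dev = np.abs(samples.r - r_bar) / r_bar
    t, p = np.meshgrid(samples.theta, samples.phi, indexing="ij")
    te = np.linspace(0.0, np.pi, n_t + 1)
    pe = np.linspace(0.0, 2.0 * np.pi, n_p + 1)
    ti = np.clip(np.digitize(t.ravel(), te) - 1, 0, n_t - 1)
    pi = np.clip(np.digitize(p.ravel(), pe) - 1, 0, n_p - 1)
    flat = ti * n_p + pi
    sums = np.bincount(flat, weights=dev.ravel(), minlength=n_t * n_p)
    counts = np.bincount(flat, minlength=n_t * n_p)
    grid = np.full(n_t * n_p, np.nan)
    nz = counts > 0
    grid[nz] = sums[nz] / counts[nz]
    fill = "none"
    if (~nz).any():
        fill = "nearest"
        tc = 0.5 * (te[:-1] + te[1:])
        pc = 0.5 * (pe[:-1] + pe[1:])
        tg, pg = np.meshgrid(tc, pc, indexing="ij")
        xyz = np.stack(
            [np.sin(tg) * np.cos(pg), np.sin(tg) * np.sin(pg), np.cos(tg)], -1
        ).reshape(-1, 3)
        tree = cKDTree(xyz[nz])
        _, near = tree.query(xyz[~nz])
        grid[~nz] = grid[nz][near]
    return GaussMap(
        grid=grid.reshape(n_t, n_p), theta_edges=te, phi_edges=pe,
        mean_radius=r_bar, fill_policy=fill,
        origin=samples.origin, axes=samples.axes,
    )


def patch_gauss_deviation(
    gauss: GaussMap, face_indices: np.ndarray, mesh: TriangleMesh
) -> float:
    """Mean Gauss-map deviation over the patch's solid angle.

    Each face centroid is mapped through the Gauss map's own origin and frame
    to its (theta, phi) cell; the cell values are averaged with face-area
    weights, so the whole surface as a patch recovers the map's global
    (solid-angle-weighted) mean deviation.
    """
    face_indices = np.asarray(face_indices, dtype=np.int64)
    if face_indices.size == 0:
        raise ValueError("empty patch")
    c = (mesh.face_centroids[face_indices] - gauss.origin) @ gauss.axes.T
    rr = np.linalg.norm(c, axis=1)
    theta = np.arccos(np.clip(c[:, 2] / rr, -1.0, 1.0))
    phi = np.mod(np.arctan2(c[:, 1], c[:, 0]), 2.0 * np.pi)
    n_t, n_p = gauss.grid.shape
    ti = np.clip(np.digitize(theta, gauss.theta_edges) - 1, 0, n_t - 1)
    pi = np.clip(np.digitize(phi, gauss.phi_edges) - 1, 0, n_p - 1)
    values = gauss.grid[ti, pi]
    return float(np.average(values, weights=mesh.face_areas[face_indices]))
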
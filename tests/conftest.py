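"""Shared fixtures: analytic meshes, oracles and one simulated sequence.

Heavy objects are session-scoped; everything is generated programmatically
(no stored fixture files).
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from spheroidkit import TriangleMesh, make_primitive


def rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Random rotation via QR of a Gaussian matrix (det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def sphere_10k():
    """Unit icosphere with >= 10k faces (subdivision 5: 20480 faces)."""
    mesh, _ = make_primitive("sphere", resolution=5, radius=1.0)
    return mesh


@pytest.fixture(scope="session")
def sphere_5k():
    mesh, _ = make_primitive("sphere", resolution=4, radius=1.0)
    return mesh


@pytest.fixture(scope="session")
def ellipsoid_mesh():
    mesh, _ = make_primitive("ellipsoid", resolution=4, radii=(1.2, 1.0, 0.8))
    return mesh


@pytest.fixture(scope="session")
def cube_mesh():
    """Unit cube subdivided to ~3k faces (exact planar geometry)."""
    mesh, _ = make_primitive("cube", resolution=4, side=1.0)
    return mesh


@pytest.fixture(scope="session")
def capped_sphere():
    """Unit sphere with a planar cap at +z occupying 15% of total area."""
    mesh, truth = make_primitive(
        "capped_sphere", resolution=4, radius=1.0, cap_fraction=0.15
    )
    return mesh, truth


@pytest.fixture(scope="session")
def faceted_sphere():
    """Subdivided (not re-projected) icosahedron: a faceted near-sphere."""
    mesh, _ = make_primitive("icosahedron", resolution=4, radius=1.0)
    return mesh


@pytest.fixture(scope="session")
def simulated_sequence():
    """Default 10-stage reduction sequence, analyzed once for all tests."""
    from spheroidkit import (
        AnalysisParams,
        ReductionSequenceSpec,
        analyze_artifact,
        simulate_reduction,
    )

    spec = ReductionSequenceSpec()
    results = simulate_reduction(spec)
    params = AnalysisParams(grid_resolution=128)
    records = [
        analyze_artifact(
            r.mesh, annotation=r.annotation, params=params,
            artifact_id=f"stage_{r.stage:02d}",
        )
        for r in results
    ]
    return spec, results, records


def plane_points(
    normal: np.ndarray,
    in_plane_a: np.ndarray,
    rng: np.random.Generator,
    n: int = 40,
    jitter: float = 0.0,
    offset: np.ndarray | None = None,
) -> np.ndarray:
    """Points on a half-plane patch spanned by ``in_plane_a`` and n x a."""
    normal = normal / np.linalg.norm(normal)
    a = in_plane_a - (in_plane_a @ normal) * normal
    a = a / np.linalg.norm(a)
    b = np.cross(normal, a)
    s = rng.uniform(0.3, 1.5, n)
    t = rng.uniform(-1.0, 1.0, n)
    pts = s[:, None] * a + t[:, None] * b
    if jitter > 0:
        pts = pts + jitter * rng.standard_normal((n, 3))
    if offset is not None:
        pts = pts + offset
    return pts


def wedge_point_sets(angle_deg: float, rng, n=40, jitter=0.0):
    """Two point sets on half-planes meeting along z with a given interior
    dihedral angle (through the material between them)."""
    alpha = np.radians(angle_deg)
    z = np.array([0.0, 0.0, 1.0])
    a1 = np.array([1.0, 0.0, 0.0])
    a2 = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    pts_a = plane_points(np.cross(a1, z), a1, rng, n=n, jitter=jitter)
    pts_b = plane_points(np.cross(a2, z), a2, rng, n=n, jitter=jitter)
    return pts_a, pts_b


@pytest.fixture(scope="session")
def dense_quadrature_oracle():
    """Independent sphericalness oracle: analytic radial functions sampled on
    a dense grid, projected on scipy's spherical harmonics by direct
    quadrature (no code shared with the package's transform)."""
    from scipy.special import sph_harm_y

    def compute(r_fn, lmax=20, n=128):
        theta = np.pi * (np.arange(n) + 0.5) / n
        phi = 2.0 * np.pi * np.arange(2 * n) / (2 * n)
        T, P = np.meshgrid(theta, phi, indexing="ij")
        u = np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], -1
        )
        r = r_fn(u)
        f = r[..., None] * u
        w = np.sin(T) * (np.pi / n) * (np.pi / n)
        E = np.zeros((lmax + 1, 3))
        for l in range(lmax + 1):
            for m in range(-l, l + 1):
                Y = sph_harm_y(l, m, T, P)
                c = np.einsum("tp,tpk->k", np.conj(Y) * w, f)
                E[l] += np.abs(c) ** 2
        first_three = E[1] / (3.0 * E.sum(axis=0))
        return float(np.abs(first_three - 1.0 / 3.0).sum())

    return compute


def make_grid_plane(n: int = 15) -> TriangleMesh:
    """Open planar grid mesh in the z = 0 plane."""
    xs = np.linspace(0.0, 1.0, n)
    xv, yv = np.meshgrid(xs, xs, indexing="ij")
    verts = np.stack([xv.ravel(), yv.ravel(), np.zeros(n * n)], axis=1)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append((a, a + n, a + 1))
            faces.append((a + 1, a + n, a + n + 1))
    return TriangleMesh(verts, np.array(faces))
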
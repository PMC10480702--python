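"""Principal frame, centres of mass and CoM/CoBB dispersion."""

import numpy as np
import pytest
import trimesh

from spheroidkit import (
    TriangleMesh,
    centre_of_mass,
    mass_centers,
    principal_frame,
)
from spheroidkit.synthgen import plane_cut

from conftest import rotation_matrix


def _subdivided_box(extents, n=3):
    tm = trimesh.creation.box(extents=extents)
    for _ in range(n):
        v, f = trimesh.remesh.subdivide(tm.vertices, tm.faces)
        tm = trimesh.Trimesh(v, f, process=False)
    return TriangleMesh.from_trimesh(tm)


def test_frame_of_axis_aligned_box_is_world_axes():
    """A 3x2x1 box's surface-tensor eigenvectors are the world axes, with
    eigenvalues ordered by face area (z-normal faces are largest)."""
    frame = principal_frame(_subdivided_box((3.0, 2.0, 1.0)))
    assert np.all(np.diff(frame.eigenvalues) <= 0)
    # each axis should align with some world axis
    overlap = np.abs(frame.axes)  # (3, 3)
    assert np.allclose(np.max(overlap, axis=1), 1.0, atol=1e-9)
    # largest eigenvalue direction = smallest box extent (z)
    assert abs(frame.axes[0] @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
    assert abs(frame.axes[2] @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-9)
    assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-9)


def test_frame_equivariance_under_rotation(rng):
    """Rotating the mesh rotates the frame axes (up to sign)."""
    box = _subdivided_box((3.0, 2.0, 1.0))
    f0 = principal_frame(box)
    for _ in range(3):
        R = rotation_matrix(rng)
        f1 = principal_frame(box.transformed(rotation=R))
        expected = f0.axes @ R.T
        dots = np.abs(np.einsum("ij,ij->i", f1.axes, expected))
        assert np.allclose(dots, 1.0, atol=1e-6)
        assert np.allclose(f1.eigenvalues, f0.eigenvalues, atol=1e-9)


def test_sphere_degenerate_spectrum_gives_world_frame(sphere_5k):
    frame = principal_frame(sphere_5k)
    assert np.allclose(frame.axes, np.eye(3), atol=1e-12)
    assert np.ptp(frame.eigenvalues) < 1e-6 * frame.eigenvalues[0]


def test_com_symmetric_solids_at_origin(sphere_5k, cube_mesh):
    for mesh in (sphere_5k, cube_mesh):
        com_mesh = mesh.transformed(translation=-centre_of_mass(mesh))
        for method in ("area-weighted", "volumetric"):
            assert np.linalg.norm(
                centre_of_mass(com_mesh, method=method)
            ) < 1e-6


def test_com_hemisphere_solid_matches_closed_forms():
    """Closed unit hemisphere (shell + disk): the surface centroid sits at
    z = 1/3, the solid centroid at z = 3/8, and the two differ."""
    sph = trimesh.creation.icosphere(subdivisions=5)
    hemi, _ = plane_cut(sph, np.array([0.0, 0.0, -1.0]), np.zeros(3))
    mesh = TriangleMesh.from_trimesh(hemi)
    assert mesh.watertight
    com_a = centre_of_mass(mesh, method="area-weighted")
    com_v = centre_of_mass(mesh, method="volumetric")
    assert com_a[2] == pytest.approx(1.0 / 3.0, abs=1e-3)
    assert com_v[2] == pytest.approx(3.0 / 8.0, abs=1e-3)
    assert abs(com_a[2] - com_v[2]) > 0.02
    # independent summation oracle for the surface centroid
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    oracle = (areas[:, None] * tri.mean(axis=1)).sum(0) / areas.sum()
    assert np.allclose(com_a, oracle, atol=1e-12)


def test_volumetric_com_requires_watertight():
    sph = trimesh.creation.icosphere(subdivisions=3)
    sph.update_faces(sph.triangles_center[:, 2] > 0)
    shell = TriangleMesh(np.asarray(sph.vertices), np.asarray(sph.faces))
    with pytest.raises(ValueError, match="watertight"):
        centre_of_mass(shell, method="volumetric")


def test_mass_centers_symmetric_solids_near_zero(sphere_10k, cube_mesh):
    assert mass_centers(sphere_10k).normalized_distance < 1e-3
    assert mass_centers(cube_mesh).normalized_distance < 1e-6


def test_mass_centers_capped_sphere_against_oracle(capped_sphere):
    """The cut sphere separates CoM and CoBB; an independent direct-sum
    oracle (world-frame extents + area centroid) gives the same value."""
    mesh, _ = capped_sphere
    mc = mass_centers(mesh, world_aabb=True)
    assert mc.normalized_distance > 0.01
    # oracle
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    com = (areas[:, None] * tri.mean(axis=1)).sum(0) / areas.sum()
    cobb = 0.5 * (mesh.vertices.min(0) + mesh.vertices.max(0))
    vol = mesh.volume
    r_eq = (3 * vol / (4 * np.pi)) ** (1 / 3)
    assert mc.raw_distance == pytest.approx(np.linalg.norm(com - cobb), abs=1e-12)
    assert mc.normalized_distance == pytest.approx(
        np.linalg.norm(com - cobb) / r_eq, abs=1e-12
    )


def test_normalized_distance_similarity_invariant(capped_sphere, rng):
    mesh, _ = capped_sphere
    d0 = mass_centers(mesh).normalized_distance
    for _ in range(5):
        R = rotation_matrix(rng)
        t = rng.uniform(-5, 5, 3)
        s = float(rng.uniform(0.1, 10.0))
        m = mesh.transformed(rotation=R, translation=t, scale=s)
        d1 = mass_centers(m).normalized_distance
        assert d1 == pytest.approx(d0, rel=1e-6)


def test_cobb_inside_bbox_com_inside_hull(capped_sphere):
    mesh, _ = capped_sphere
    mc = mass_centers(mesh)
    lo, hi = mesh.vertices.min(0), mesh.vertices.max(0)
    assert np.all(mc.cobb >= lo - 1e-9) and np.all(mc.cobb <= hi + 1e-9)
    # convex solid: containment test via the hull's face planes
    hull = mesh._tm.convex_hull
    d = (mc.com - hull.triangles_center[:, :]) * hull.face_normals
    assert np.all(d.sum(axis=1) <= 1e-9)


def test_bump_strictly_increases_dispersion(sphere_5k):
    """Growing a one-sided bump monotonically shifts CoBB away from CoM."""
    dists = []
    for height in (0.0, 0.05, 0.1, 0.2):
        v = sphere_5k.vertices.copy()
        sel = v[:, 2] > 0.9
        scale = 1.0 + height * (v[sel, 2] - 0.9) / 0.1
        v[sel] = v[sel] * scale[:, None]
        m = TriangleMesh(v, sphere_5k.faces)
        dists.append(mass_centers(m, world_aabb=True).raw_distance)
    assert all(np.diff(dists) > 0)
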
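"""Radial parametrization, sphericalness, reconstruction and Gauss maps."""

import numpy as np
import pytest
import trimesh

from spheroidkit import (
    TriangleMesh,
    NotStarShapedError,
    gauss_map,
    make_primitive,
    patch_gauss_deviation,
    radial_parametrization,
    spharm_expand,
    spharm_reconstruct,
)
from spheroidkit.spharm import reconstruction_rms_error

from conftest import rotation_matrix


@pytest.fixture(scope="module")
def sphere2_samples():
    mesh = TriangleMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=4, radius=2.0)
    )
    return mesh, radial_parametrization(mesh, 128)


def test_sphere_radius_recovered(sphere2_samples):
    _, samples = sphere2_samples
    assert np.all(np.abs(samples.r - 2.0) < 0.01)
    assert samples.mean_radius == pytest.approx(2.0, rel=1e-3)


def test_ellipsoid_radii_at_poles_and_equator(ellipsoid_mesh):
    samples = radial_parametrization(ellipsoid_mesh, 128)
    # poles (theta ~ 0, pi) -> c = 0.8; equator phi ~ 0 -> a = 1.2
    assert samples.r[0].mean() == pytest.approx(0.8, rel=5e-3)
    assert samples.r[-1].mean() == pytest.approx(0.8, rel=5e-3)
    i_eq = len(samples.theta) // 2
    assert samples.r[i_eq, 0] == pytest.approx(1.2, rel=5e-3)


def test_capped_sphere_radius_matches_ray_plane_form(capped_sphere):
    """Near the pole the ray hits the cap plane: r = z0 / cos(theta)."""
    mesh, truth = capped_sphere
    samples = radial_parametrization(mesh, 128, origin=np.zeros(3))
    z0 = 1.0 - truth["cap_height"]
    t0 = samples.theta[0]
    assert samples.r[0].mean() == pytest.approx(z0 / np.cos(t0), rel=1e-3)


def test_non_star_shaped_rejected():
    torus = TriangleMesh.from_trimesh(trimesh.creation.torus(2.0, 0.5))
    with pytest.raises(NotStarShapedError):
        radial_parametrization(torus, 64)


def test_sphere_anchor_first_three(sphere_10k):
    """A sphere's three normalised degree-1 coefficients are 1/3 each."""
    samples = radial_parametrization(sphere_10k, 256)
    exp = spharm_expand(samples, lmax=20)
    assert np.allclose(exp.first_three, 1.0 / 3.0, atol=1e-3)
    assert exp.sphericalness_deviation < 3e-3


def test_sphere_invariance_under_rotation_and_scaling(sphere_5k, rng):
    base = spharm_expand(radial_parametrization(sphere_5k, 128), 20)
    for _ in range(3):
        m = sphere_5k.transformed(
            rotation=rotation_matrix(rng), scale=float(rng.uniform(0.2, 5.0))
        )
        exp = spharm_expand(radial_parametrization(m, 128), 20)
        assert exp.sphericalness_deviation == pytest.approx(
            base.sphericalness_deviation, abs=1e-6
        )


def test_ordering_cube_ellipsoid_sphere_vs_oracle(
    cube_mesh, ellipsoid_mesh, sphere_10k, dense_quadrature_oracle
):
    """Sphericalness orders cube > ellipsoid(1.2,1,0.8) > sphere, and each
    mesh-pipeline value matches the analytic dense-quadrature oracle."""
    dev = {}
    for name, mesh, grid in (
        ("cube", cube_mesh, 128),
        ("ellipsoid", ellipsoid_mesh, 128),
        ("sphere", sphere_10k, 128),
    ):
        samples = radial_parametrization(mesh, grid)
        dev[name] = spharm_expand(samples, 20).sphericalness_deviation

    oracle = {
        "cube": dense_quadrature_oracle(lambda u: 0.5 / np.abs(u).max(-1)),
        "ellipsoid": dense_quadrature_oracle(
            lambda u: 1.0
            / np.sqrt((u[..., 0] / 1.2) ** 2 + u[..., 1] ** 2 + (u[..., 2] / 0.8) ** 2)
        ),
        "sphere": dense_quadrature_oracle(lambda u: np.ones(u.shape[:-1])),
    }
    assert dev["cube"] > dev["ellipsoid"] > dev["sphere"]
    assert dev["cube"] == pytest.approx(oracle["cube"], rel=0.01)
    assert dev["ellipsoid"] == pytest.approx(oracle["ellipsoid"], rel=0.01)
    assert dev["sphere"] == pytest.approx(oracle["sphere"], abs=1e-4)


def test_translation_invariance_via_com_centering(capped_sphere):
    mesh, _ = capped_sphere
    d0 = spharm_expand(radial_parametrization(mesh, 128), 20)
    moved = mesh.transformed(translation=np.array([5.0, -2.0, 7.0]))
    d1 = spharm_expand(radial_parametrization(moved, 128), 20)
    assert d1.sphericalness_deviation == pytest.approx(
        d0.sphericalness_deviation, rel=1e-9
    )


def test_icosphere_deviation_converges_to_zero():
    """Finer icospheres are closer to the sphere: deviation decreases
    monotonically over refinement levels."""
    devs = []
    for sub in (2, 3, 4, 5):
        mesh, _ = make_primitive("sphere", resolution=sub)
        devs.append(
            spharm_expand(radial_parametrization(mesh, 64), 20).sphericalness_deviation
        )
    assert all(np.diff(devs) < 0)


def test_reconstruction_sphere_degree_one(sphere2_samples):
    mesh, samples = sphere2_samples
    exp = spharm_expand(samples, 20)
    err = reconstruction_rms_error(exp, samples, l=1)
    assert err / 2.0 < 0.01  # RMS radial error under 1% of the radius


def test_reconstruction_error_non_increasing(capped_sphere):
    mesh, _ = capped_sphere
    samples = radial_parametrization(mesh, 128)
    exp = spharm_expand(samples, 25)
    errs = [reconstruction_rms_error(exp, samples, l=l) for l in range(26)]
    assert all(np.diff(errs) <= 1e-12)


def test_reconstruction_faceted_sphere_improves(faceted_sphere):
    samples = radial_parametrization(faceted_sphere, 128)
    exp = spharm_expand(samples, 25)
    assert reconstruction_rms_error(exp, samples, 25) < reconstruction_rms_error(
        exp, samples, 5
    )


def test_reconstruct_returns_watertight_mesh(sphere2_samples):
    _, samples = sphere2_samples
    exp = spharm_expand(samples, 20)
    rec = spharm_reconstruct(exp, l=1, grid_resolution=48)
    assert rec.watertight
    r = np.linalg.norm(rec.vertices, axis=1)
    assert np.abs(r - 2.0).max() < 0.05
    with pytest.raises(ValueError, match="exceeds"):
        spharm_reconstruct(exp, l=21)


def test_gauss_map_sphere_flat(sphere_10k):
    samples = radial_parametrization(sphere_10k, 256)
    gm = gauss_map(samples)
    assert gm.grid.shape == (100, 100)
    assert np.all(gm.grid < 1e-3)


def test_gauss_map_localizes_cap(capped_sphere):
    """The arg-max deviation cell sits within 2 cells of the cap centre
    direction (the +z pole in the unrotated frame)."""
    mesh, _ = capped_sphere
    samples = radial_parametrization(mesh, 256, origin=np.zeros(3))
    gm = gauss_map(samples)
    i_max, _ = np.unravel_index(np.argmax(gm.grid), gm.grid.shape)
    assert i_max <= 2


def test_gauss_map_aggregation_consistent(capped_sphere):
    """The grid mean equals the sample mean of |r - r_mean|/r_mean up to
    binning (cell-count) effects."""
    mesh, _ = capped_sphere
    samples = radial_parametrization(mesh, 256)
    gm = gauss_map(samples)
    dev = np.abs(samples.r - samples.mean_radius) / samples.mean_radius
    assert gm.grid.mean() == pytest.approx(dev.mean(), rel=0.05)


def test_patch_gauss_deviation_cap_vs_complement(capped_sphere):
    mesh, truth = capped_sphere
    samples = radial_parametrization(mesh, 256)
    gm = gauss_map(samples)
    cap_idx = truth["cap_face_indices"]
    rest = np.setdiff1d(np.arange(mesh.n_faces), cap_idx)
    d_cap = patch_gauss_deviation(gm, cap_idx, mesh)
    d_rest = patch_gauss_deviation(gm, rest, mesh)
    assert d_cap > d_rest
    # an untouched band away from the cap deviates far less than the cap
    centro = mesh.face_centroids
    band = np.flatnonzero(centro[:, 2] < -0.5)
    assert patch_gauss_deviation(gm, band, mesh) < 0.1 * d_cap


def test_patch_gauss_deviation_whole_surface(capped_sphere):
    mesh, _ = capped_sphere
    samples = radial_parametrization(mesh, 256)
    gm = gauss_map(samples)
    whole = patch_gauss_deviation(gm, np.arange(mesh.n_faces), mesh)
    assert whole == pytest.approx(gm.mean_deviation, rel=0.10)
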
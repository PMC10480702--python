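"""Synthetic fixtures and a geometric reduction-sequence simulator.

The simulator emulates the proposed spheroid reduction geometry: every stage
is a near-spherical core with one reserved planar *primary facet* whose area
proportion follows a prescribed decreasing schedule, surrounded by planar
"flake" facets cut around the facet's perimeter at progressively steeper
platform angles.  Later stages therefore have a smaller primary surface,
higher platform angles and shapes closer to a sphere — known ground truth
for every metric the measurement modules compute.  Cuts are boolean plane
cuts: the simulator is a geometric emulation, not a fracture-mechanics
model.

A per-stage random surface texture (small radial vertex noise, amplitude
drawn independently per stage) decouples small-scale roughness from the
reduction schedule, mirroring assemblages where heavily reduced pieces can
remain heavily faceted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import brentq

from .mesh import TriangleMesh
from .surfaces import SurfacePatch, save_annotation

__all__ = [
    "make_primitive",
    "plane_cut",
    "cap_height_for_fraction",
    "ReductionSequenceSpec",
    "StageResult",
    "simulate_reduction",
    "write_run",
]


# --------------------------------------------------------------------------
# plane cutting with explicit cap triangulation (convex solids only)
# --------------------------------------------------------------------------

def _order_loop(edges: np.ndarray) -> np.ndarray:
    """Order an edge soup (n, 2) into a single closed vertex loop."""
    nxt: dict[int, list[int]] = {}
    for a, b in edges:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    start = int(edges[0, 0])
    loop = [start]
    prev = -1
    while True:
        cands = [v for v in nxt[loop[-1]] if v != prev]
        if not cands:
            raise ValueError("open boundary loop; cannot cap cut")
        prev, cur = loop[-1], cands[0]
        if cur == start:
            break
        loop.append(cur)
        if len(loop) > len(edges) + 1:
            raise ValueError("boundary is not a single loop; cannot cap cut")
    return np.array(loop, dtype=np.int64)


def plane_cut(
    tm: trimesh.Trimesh, normal: np.ndarray, point: np.ndarray,
    target_edge: float | None = None,
) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Cut away the half-space ``normal . (x - point) > 0`` and cap the hole.

    Valid for convex solids (the cross-section is a single convex polygon).
    The cap is triangulated as concentric rings; ``target_edge`` sets the
    radial ring spacing (default: the boundary's mean edge length), keeping
    cap face sizes comparable to the surrounding mesh.  Returns the new mesh
    and the indices of the cap faces.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    point = np.asarray(point, dtype=float)
    sliced = trimesh.intersections.slice_mesh_plane(
        tm, plane_normal=-normal, plane_origin=point, cap=False
    )
    if len(sliced.faces) == 0:
        raise ValueError("cut removed the entire mesh")
    sliced.merge_vertices()  # the slicer duplicates vertices along the cut
    edges = sliced.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:  # plane missed the solid
        return sliced, np.empty(0, dtype=np.int64)
    loop = _order_loop(boundary)
    verts = sliced.vertices
    centre = verts[loop].mean(axis=0)
    # triangulate the (convex, planar) cap as concentric rings so its faces
    # have edge lengths comparable to the boundary: large fan triangles would
    # distort face-level metrics and ray-casting heuristics downstream
    ring_pts = verts[loop]
    edge_len = np.linalg.norm(ring_pts - np.roll(ring_pts, -1, axis=0), axis=1).mean()
    spacing = max(edge_len, target_edge or 0.0)
    mean_r = np.linalg.norm(ring_pts - centre, axis=1).mean()
    n_rings = max(1, int(round(mean_r / max(spacing, 1e-12))))
    nb = len(loop)

    new_verts = [verts]
    vc = len(verts)
    centre_id = vc
    new_verts.append(centre[None])
    ring_ids = []  # innermost ... outermost(= loop)
    next_id = vc + 1
    for i in range(1, n_rings):
        t = i / n_rings
        new_verts.append(centre + t * (ring_pts - centre))
        ring_ids.append(np.arange(next_id, next_id + nb))
        next_id += nb
    ring_ids.append(loop)

    cap_faces = []
    inner = ring_ids[0]
    for j in range(nb):
        cap_faces.append((centre_id, inner[j], inner[(j + 1) % nb]))
    for a, b in zip(ring_ids[:-1], ring_ids[1:]):
        for j in range(nb):
            j1 = (j + 1) % nb
            cap_faces.append((a[j], b[j], b[j1]))
            cap_faces.append((a[j], b[j1], a[j1]))
    cap = np.array(cap_faces, dtype=np.int64)
    new_verts = np.vstack(new_verts)
    # orient cap triangles so their normals point along the cut normal
    e1 = new_verts[cap[:, 1]] - new_verts[cap[:, 0]]
    e2 = new_verts[cap[:, 2]] - new_verts[cap[:, 0]]
    flip = np.einsum("ij,j->i", np.cross(e1, e2), normal) < 0
    cap[flip] = cap[flip][:, [0, 2, 1]]
    faces = np.vstack([sliced.faces, cap])
    out = trimesh.Trimesh(new_verts, faces, process=False)
    cap_idx = np.arange(len(sliced.faces), len(faces), dtype=np.int64)
    return out, cap_idx


def cap_height_for_fraction(radius: float, fraction: float) -> float:
    """Cap height h such that the planar facet of a once-cut sphere occupies
    ``fraction`` of the solid's total surface area: f = h / (2R + h)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return 2.0 * radius * fraction / (1.0 - fraction)


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def make_primitive(
    kind: str, resolution: int = 4, **params
) -> tuple[TriangleMesh, dict]:
    """Watertight analytic fixture plus its ground-truth record.

    kinds: ``sphere`` (radius), ``ellipsoid`` (radii), ``cube`` (side),
    ``icosahedron`` (radius; subdivided but *not* re-projected, i.e. a
    faceted sphere), ``capped_sphere`` (radius, cap_fraction; ground truth
    includes the cap face indices and the exact cap height).
    """
    if kind == "sphere":
        radius = float(params.get("radius", 1.0))
        if radius <= 0:
            raise ValueError("radius must be positive")
        tm = trimesh.creation.icosphere(subdivisions=resolution, radius=radius)
        truth = {
            "area": 4.0 * np.pi * radius**2,
            "volume": 4.0 / 3.0 * np.pi * radius**3,
            "radius": radius,
        }
        return TriangleMesh.from_trimesh(tm), truth

    if kind == "ellipsoid":
        radii = np.asarray(params.get("radii", (1.2, 1.0, 0.8)), dtype=float)
        if radii.shape != (3,) or np.any(radii <= 0):
            raise ValueError("radii must be three positive numbers")
        tm = trimesh.creation.icosphere(subdivisions=resolution)
        tm.vertices = tm.vertices * radii
        truth = {
            "volume": 4.0 / 3.0 * np.pi * float(np.prod(radii)),
            "radii": tuple(radii),
        }
        return TriangleMesh.from_trimesh(tm), truth

    if kind == "cube":
        side = float(params.get("side", 1.0))
        if side <= 0:
            raise ValueError("side must be positive")
        tm = trimesh.creation.box(extents=(side, side, side))
        for _ in range(resolution):
            v, f = trimesh.remesh.subdivide(tm.vertices, tm.faces)
            tm = trimesh.Trimesh(v, f, process=False)
        truth = {"area": 6.0 * side**2, "volume": side**3, "side": side}
        return TriangleMesh.from_trimesh(tm), truth

    if kind == "icosahedron":
        radius = float(params.get("radius", 1.0))
        tm = trimesh.creation.icosahedron()
        tm.vertices = tm.vertices / np.linalg.norm(tm.vertices, axis=1).max() * radius
        for _ in range(resolution):
            v, f = trimesh.remesh.subdivide(tm.vertices, tm.faces)
            tm = trimesh.Trimesh(v, f, process=False)
        return TriangleMesh.from_trimesh(tm), {"radius": radius}

    if kind == "capped_sphere":
        radius = float(params.get("radius", 1.0))
        fraction = float(params.get("cap_fraction", 0.15))
        axis = np.asarray(params.get("axis", (0.0, 0.0, 1.0)), dtype=float)
        axis = axis / np.linalg.norm(axis)
        h = cap_height_for_fraction(radius, fraction)
        tm = trimesh.creation.icosphere(subdivisions=resolution, radius=radius)
        cut, cap_idx = plane_cut(tm, axis, axis * (radius - h))
        truth = {
            "radius": radius,
            "cap_fraction": fraction,
            "cap_height": h,
            "cap_face_indices": cap_idx,
            "axis": tuple(axis),
        }
        return TriangleMesh.from_trimesh(cut), truth

    raise ValueError(f"unknown primitive kind {kind!r}")


# --------------------------------------------------------------------------
# reduction-sequence simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionSequenceSpec:
    """Study conditions for one synthetic reduction sequence.

    The primary-facet schedule controls reduction intensity directly; flake
    count, depth and platform-angle progression control how the remainder of
    the surface evolves.  ``texture_amplitude_range`` bounds the per-stage
    radial surface noise (as a fraction of the stage radius) that stands in
    for cortex, pecking and residual scars.
    """

    base_radius: float = 40.0  # mm, typical spheroid scale
    n_stages: int = 10
    primary_cap_fraction_schedule: tuple[float, ...] = tuple(
        np.geomspace(0.30, 0.03, 10).tolist()
    )
    flakes_per_stage: int = 8
    flake_depth_fraction: float = 0.015  # of stage radius, at the first stage
    platform_angle_range: tuple[float, float] = (100.0, 150.0)  # degrees
    texture_amplitude_range: tuple[float, float] = (0.002, 0.012)
    stage_shrink: float = 0.97  # radius factor per stage (material removal)
    resolution: int = 4  # icosphere subdivisions
    rng_seed: int = 42

    def __post_init__(self):
        sched = np.asarray(self.primary_cap_fraction_schedule, dtype=float)
        if len(sched) != self.n_stages:
            raise ValueError("schedule length must equal n_stages")
        if np.any(sched <= 0) or np.any(sched >= 1):
            raise ValueError("cap fractions must lie in (0, 1)")
        if np.any(np.diff(sched) >= 0):
            raise ValueError("cap fraction schedule must be strictly decreasing")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class StageResult:
    stage: int
    mesh: TriangleMesh
    annotation: SurfacePatch
    truth: dict = field(default_factory=dict)


def _build_stage(
    spec: ReductionSequenceSpec,
    stage: int,
    azimuth_offset: float,
    azimuth_jitter: np.ndarray,
    texture_amp: float,
    rng: np.random.Generator,
) -> StageResult:
    R = spec.base_radius * spec.stage_shrink**stage
    F = spec.primary_cap_fraction_schedule[stage]
    F0 = spec.primary_cap_fraction_schedule[0]
    angles = np.linspace(*spec.platform_angle_range, spec.n_stages)
    theta_platform = float(angles[stage])
    gamma = np.radians(180.0 - theta_platform)  # flake normal vs facet normal

    h0 = cap_height_for_fraction(R, F)
    z0 = R - h0
    rho = float(np.sqrt(max(R**2 - z0**2, 0.0)))
    depth = spec.flake_depth_fraction * R * np.sqrt(F / F0)

    base = trimesh.creation.icosphere(subdivisions=spec.resolution, radius=R)
    base_edge = float(base.edges_unique_length.mean())

    cut_log = []
    cut_planes: list[tuple[np.ndarray, np.ndarray]] = []
    mesh_tm = base
    K = spec.flakes_per_stage
    for j in range(K):
        az = azimuth_offset + 2.0 * np.pi * (j + azimuth_jitter[j] * 0.4) / K
        u = np.array([np.cos(az), np.sin(az), 0.0])
        n_f = np.sin(gamma) * u + np.cos(gamma) * np.array([0.0, 0.0, 1.0])
        q = u * (rho - depth) + np.array([0.0, 0.0, z0])
        cut_planes.append((n_f, q))
        mesh_tm, _ = plane_cut(mesh_tm, n_f, q, target_edge=base_edge)
        cut_log.append({
            "azimuth": float(az), "gamma_deg": float(np.degrees(gamma)),
            "depth": float(depth),
        })

    # surface texture, applied before the primary cut so the root-find below
    # matches the scheduled fraction on the textured solid.  Radial noise on
    # the uncut "cortex" region only: flake scars are smooth conchoidal
    # surfaces, so every cut facet (and its one-ring, which carries the rim
    # dihedrals) keeps its exact plane.  The noise is high-passed on the
    # vertex graph: subtracting the neighbour mean (twice) strips the smooth
    # component, so the texture drives local plane-deviation roughness
    # without adding low-order shape energy that would contaminate the
    # sphericalness of the stage.
    if texture_amp > 0:
        verts = mesh_tm.vertices.copy()
        protect = np.zeros(len(verts), dtype=bool)
        centroids = mesh_tm.triangles_center
        normals = mesh_tm.face_normals
        facet_vids = []
        for n_f, q in cut_planes:
            on_plane = (
                (np.abs(normals @ n_f - 1.0) < 1e-6)
                & (np.abs((centroids - q) @ n_f) < 1e-6 * R)
            )
            facet_vids.append(np.unique(mesh_tm.faces[on_plane]))
        # the primary facet does not exist yet; protect the band of vertices
        # that the primary plane and its one-ring will pass through
        near_primary = np.flatnonzero(verts[:, 2] > z0 - 2.0 * base_edge)
        facet_vids.append(near_primary)
        fv = np.unique(np.concatenate(facet_vids))
        protect[fv] = True
        touch = np.isin(mesh_tm.faces, fv).any(axis=1)
        protect[np.unique(mesh_tm.faces[touch])] = True
        g = rng.standard_normal(len(verts))
        edges = mesh_tm.edges_sorted
        for _ in range(2):
            acc = np.zeros(len(verts))
            cnt = np.zeros(len(verts))
            np.add.at(acc, edges[:, 0], g[edges[:, 1]])
            np.add.at(acc, edges[:, 1], g[edges[:, 0]])
            np.add.at(cnt, edges[:, 0], 1.0)
            np.add.at(cnt, edges[:, 1], 1.0)
            g = g - acc / np.maximum(cnt, 1.0)
        g = g / max(g.std(), 1e-12)
        g[protect] = 0.0
        mesh_tm = trimesh.Trimesh(
            verts * (1.0 + texture_amp * g)[:, None],
            np.asarray(mesh_tm.faces), process=False,
        )

    # final primary cut: root-find the height so the measured facet fraction
    # matches the schedule on the flaked, textured solid
    z_axis = np.array([0.0, 0.0, 1.0])

    def measured_fraction(h):
        cut, idx = plane_cut(mesh_tm, z_axis, z_axis * (R - h),
                             target_edge=base_edge)
        if len(idx) == 0:
            return 0.0
        return cut.area_faces[idx].sum() / cut.area
    lo, hi = 0.25 * h0, min(2.5 * h0, 1.9 * R)
    try:
        h_star = brentq(
            lambda h: measured_fraction(h) - F, lo, hi, xtol=1e-5 * R
        )
    except ValueError as exc:
        raise RuntimeError(
            f"stage {stage}: could not match primary fraction {F:.4f}"
        ) from exc
    final, cap_idx = plane_cut(mesh_tm, z_axis, z_axis * (R - h_star),
                               target_edge=base_edge)
    mesh = TriangleMesh(np.asarray(final.vertices), np.asarray(final.faces))

    cap_area = mesh.face_areas[cap_idx].sum()
    truth = {
        "stage": stage,
        "radius": R,
        "target_fraction": float(F),
        "constructed_fraction": float(cap_area / mesh.total_area),
        "platform_angle_target": theta_platform,
        "natural_rim_angle": float(180.0 - np.degrees(np.arccos((R - h_star) / R))),
        "cap_height": float(h_star),
        "texture_amplitude": float(texture_amp),
        "cuts": cut_log,
    }
    annotation = SurfacePatch(
        label="primary", face_indices=cap_idx,
        artifact_id=f"stage_{stage:02d}",
    )
    return StageResult(stage=stage, mesh=mesh, annotation=annotation, truth=truth)


def simulate_reduction(spec: ReductionSequenceSpec) -> list[StageResult]:
    """Build every stage of a reduction sequence, deterministically.

    Stages are independent geometric states of one reduction model; all
    randomness (flake azimuths, texture amplitudes, texture noise) derives
    from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    results = []
    for s in range(spec.n_stages):
        offset = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.uniform(-0.5, 0.5, size=spec.flakes_per_stage)
        amp = rng.uniform(*spec.texture_amplitude_range)
        results.append(_build_stage(spec, s, offset, jitter, amp, rng))
    return results


def write_run(
    spec: ReductionSequenceSpec, results: list[StageResult], out_dir: str | Path
) -> Path:
    """Export stage meshes (PLY), annotations (JSON) and ground truth (CSV)
    into ``out_dir/run_<spec digest>``."""
    import pandas as pd

    run = Path(out_dir) / f"run_{spec.digest()}"
    run.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        stem = f"stage_{res.stage:02d}"
        res.mesh._tm.export(run / f"{stem}.ply")
        save_annotation(res.annotation, run / f"{stem}.json")
        row = {k: v for k, v in res.truth.items() if k != "cuts"}
        rows.append(row)
    pd.DataFrame(rows).to_csv(run / "ground_truth.csv", index=False)
    with open(run / "spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return run
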
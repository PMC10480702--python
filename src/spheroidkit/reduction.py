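"""Per-artifact metric records, reduction-trend regressions and the
three-hypothesis report.

``analyze_artifact`` composes every measurement module with one parameter
set; ``fit_trends`` regresses each shape metric against the
reduction-intensity proxy (primary-surface area proportion) with closed-form
OLS plus Spearman rank correlation; ``hypothesis_report`` translates the
fitted trends into the three competing readings of spheroids — percussor
(smoother AND more spherical with reduction), expedient core (possible
smoothing, no sphericalness trend) or intentionally shaped item (more
spherical without necessarily smoother).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import mass_centers, principal_frame
from .mesh import TriangleMesh, mesh_summary
from .roughness import surface_curvature
from .spharm import gauss_map, radial_parametrization, spharm_expand
from .surfaces import SurfacePatch, patch_metrics, reduction_proxy

#: metrics regressed against the proxy, in reporting order
TREND_METRICS = (
    "mean_roughness_normalized",
    "com_cobb_normalized",
    "sphericalness_deviation",
    "primary_platform_angle",
)


@dataclass(frozen=True)
class AnalysisParams:
    area_fraction: float = 0.0005  # roughness neighbourhood, fraction of area
    lmax: int = 20
    grid_resolution: int = 256  # radial parametrization grid
    gauss_shape: tuple[int, int] = (100, 100)
    com_method: str = "area-weighted"


@dataclass
class MetricRecord:
    """One artifact's full metric row."""

    artifact_id: str
    area: float  # mm^2
    volume: float | None  # mm^3
    r_eq: float  # mm
    mean_roughness_normalized: float
    com_cobb_normalized: float
    sphericalness_deviation: float
    primary_area_proportion: float | None = None
    primary_platform_angle: float | None = None
    primary_gauss_deviation: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        d = asdict(self)
        d.pop("provenance")
        return d


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        super().__init__(f"analysis stage {stage!r} failed: {original}")


def analyze_artifact(
    mesh: TriangleMesh,
    annotation: SurfacePatch | None = None,
    params: AnalysisParams | None = None,
    artifact_id: str = "artifact",
) -> MetricRecord:
    """Run all measurement modules on one mesh with a single parameter set.

    Deterministic given inputs and parameters.  Without a primary-surface
    annotation the proxy fields are left absent.
    """
    p = params or AnalysisParams()
    stage = "summary"
    try:
        summary = mesh_summary(mesh)
        stage = "principal_frame"
        frame = principal_frame(mesh)
        stage = "mass_centers"
        mc = mass_centers(mesh, frame=frame, com_method=p.com_method)
        stage = "roughness"
        curv = surface_curvature(mesh, area_fraction=p.area_fraction)
        stage = "radial_parametrization"
        samples = radial_parametrization(mesh, p.grid_resolution, frame=frame)
        stage = "spharm"
        expansion = spharm_expand(samples, lmax=p.lmax)
        stage = "gauss_map"
        gauss = gauss_map(samples, shape=p.gauss_shape)
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise StageError(stage, exc) from exc

    record = MetricRecord(
        artifact_id=artifact_id,
        area=summary.total_area,
        volume=summary.volume,
        r_eq=summary.r_eq,
        mean_roughness_normalized=curv.mean_roughness_normalized,
        com_cobb_normalized=mc.normalized_distance,
        sphericalness_deviation=expansion.sphericalness_deviation,
        provenance={
            "source": mesh.source,
            "params": asdict(p),
            "n_faces": mesh.n_faces,
        },
    )
    if annotation is None:
        return record
    try:
        patch = patch_metrics(mesh, annotation, gauss=gauss)
    except Exception as exc:  # noqa: BLE001
        raise StageError("patch_metrics", exc) from exc
    record.primary_area_proportion = reduction_proxy(patch)
    record.primary_platform_angle = patch.platform_angle
    record.primary_gauss_deviation = patch.gauss_deviation
    return record


@dataclass(frozen=True)
class TrendResult:
    metric: str
    slope: float
    intercept: float
    r_squared: float
    spearman_rho: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, R^2."""
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    # relative tolerance: a numerically-constant column has no variance
    if sxx <= (1e-12 * max(1.0, np.abs(x).max())) ** 2 * len(x):
        raise ValueError("zero-variance regressor")
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy <= (1e-12 * max(1.0, np.abs(y).max())) ** 2 * len(y):
        r2 = 0.0
    else:
        r2 = (sxy * sxy) / (sxx * syy)
    return float(slope), float(intercept), float(r2)


def fit_trends(
    records: Sequence[MetricRecord],
    metrics: Sequence[str] = TREND_METRICS,
) -> list[TrendResult]:
    """Regress each metric on the reduction proxy across artifacts.

    Uses raw (untransformed) variables, closed-form OLS and Spearman rank
    correlation.  Records without a primary annotation are skipped; at least
    three usable records are required.
    """
    usable = [r for r in records if r.primary_area_proportion is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 records with a primary annotation, got {len(usable)}")
    x = np.array([r.primary_area_proportion for r in usable], dtype=float)
    out = []
    for name in metrics:
        y = np.array(
            [getattr(r, name, None) for r in usable], dtype=float
        )
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        slope, intercept, r2 = _ols(x[ok], y[ok])
        if np.ptp(y[ok]) == 0.0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(x[ok], y[ok]).statistic)
        out.append(TrendResult(name, slope, intercept, r2, rho, int(ok.sum())))
    return out


@dataclass(frozen=True)
class HypothesisReport:
    verdict: str
    roughness_improves: bool
    sphericalness_improves: bool
    mass_evenness_improves: bool | None
    statements: tuple[str, ...]


def hypothesis_report(
    trends: Sequence[TrendResult], rho_threshold: float = 0.5
) -> HypothesisReport:
    """Rule-based verdict over the fitted trends.

    A metric "improves with reduction" when it falls as the proxy falls,
    i.e. its Spearman rho against the proxy is positive and at least
    ``rho_threshold`` in magnitude.  No significance tests are invented: the
    report is descriptive, exactly as the underlying argument is.
    """
    by_name = {t.metric: t for t in trends}
    try:
        rough = by_name["mean_roughness_normalized"]
        sph = by_name["sphericalness_deviation"]
    except KeyError as exc:
        raise ValueError(f"missing trend for {exc.args[0]}") from exc
    com = by_name.get("com_cobb_normalized")

    rough_up = rough.spearman_rho >= rho_threshold
    sph_up = sph.spearman_rho >= rho_threshold
    com_up = None if com is None else com.spearman_rho >= rho_threshold

    if sph_up and rough_up:
        verdict = "percussor-consistent pattern"
    elif sph_up:
        verdict = "intentional-shaping pattern"
    elif rough_up:
        verdict = "core-consistent pattern"
    else:
        verdict = "no reduction patterning detected"

    statements = (
        f"surface roughness {'falls' if rough_up else 'shows no consistent trend'} "
        f"with reduction (Spearman rho vs proxy = {rough.spearman_rho:+.3f}, "
        f"R^2 = {rough.r_squared:.4f})",
        f"sphericalness deviation {'falls' if sph_up else 'shows no consistent trend'} "
        f"with reduction (Spearman rho vs proxy = {sph.spearman_rho:+.3f}, "
        f"R^2 = {sph.r_squared:.4f})",
    ) + (
        ()
        if com is None
        else (
            f"CoM-CoBB separation {'falls' if com_up else 'shows no consistent trend'} "
            f"with reduction (Spearman rho vs proxy = {com.spearman_rho:+.3f}, "
            f"R^2 = {com.r_squared:.4f})",
        )
    )
    return HypothesisReport(
        verdict=verdict,
        roughness_improves=rough_up,
        sphericalness_improves=sph_up,
        mass_evenness_improves=com_up,
        statements=statements,
    )


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def trends_to_frame(trends: Sequence[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in trends])
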
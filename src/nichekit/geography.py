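"""Centroid migration, rank tests, and protected-area gap analysis.

The geographic center of the high-suitability class is the area-weighted
mean of cell-center coordinates (weights = geodesic cell areas), consecutive
displacements are great-circle (haversine) distances, and per-scenario
distance samples are compared with the Kruskal-Wallis rank test (mid-ranks
for ties, chi-square reference distribution).

Gap analysis designates the moderate + high suitability classes as the
priority conservation area and measures what fraction of it falls inside
protected-area polygons; a priority cell counts as covered iff its center
lies inside a polygon (error bounded by one ring of cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.stats import chi2, rankdata
from shapely.ops import unary_union

from .dynamics import HIGH, MODERATE, ClassifiedRaster
from .grids import EARTH_RADIUS_KM

logger = logging.getLogger("nichekit")


# ---------------------------------------------------------------------------
# Centroids and distances
# ---------------------------------------------------------------------------

def centroid_high(c: ClassifiedRaster, klass: int = HIGH) -> tuple[float, float]:
    """Area-weighted centroid (lon, lat) of the high-suitability cells.

    Longitudes are averaged arithmetically (no antimeridian handling: the
    supported extents never span it).
    """
    mask = c.valid & (c.classes == klass)
    if not mask.any():
        raise ValueError("no cells in the requested class")
    rows, cols = np.nonzero(mask)
    lon, lat = c.spec.cell_center(rows, cols)
    w = c.spec.cell_area_grid()[rows, cols]
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points."""
    lon1, lat1 = np.deg2rad(a)
    lon2, lat2 = np.deg2rad(b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


@dataclass
class CentroidTrack:
    scenario: str
    periods: list[str]
    centroids: list[tuple[float, float]]
    distances_km: list[float]


def centroid_track(
    scenario: str,
    classified_by_period: dict[str, ClassifiedRaster],
    period_order: list[str],
) -> CentroidTrack:
    """Centroid per period plus consecutive great-circle displacements."""
    cents = [centroid_high(classified_by_period[p]) for p in period_order]
    dists = [haversine_km(a, b) for a, b in zip(cents[:-1], cents[1:])]
    return CentroidTrack(scenario, list(period_order), cents, dists)


# ---------------------------------------------------------------------------
# Kruskal-Wallis rank test
# ---------------------------------------------------------------------------

@dataclass
class KWResult:
    h: float
    df: int
    p_value: float
    mean_ranks: list[float]
    tie_correction: float


def kruskal_wallis(groups: list[list[float]]) -> KWResult:
    """Kruskal-Wallis H with mid-ranks, tie correction, chi-square p-value.

    H = [12 / (N (N+1))] * sum n_i * Rbar_i^2 - 3 (N+1), divided by the tie
    factor 1 - sum(t^3 - t) / (N^3 - N).  All-tied input gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = rankdata(pooled)
    mean_ranks = []
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos: pos + g.size]
        pos += g.size
        mean_ranks.append(float(r.mean()))
        h += g.size * r.mean() ** 2
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum()) / (n_total**3 - n_total))
    if tie <= 0:
        # every value identical
        return KWResult(0.0, len(groups) - 1, 1.0, mean_ranks, 0.0)
    h /= tie
    df = len(groups) - 1
    p = float(chi2.sf(h, df))
    return KWResult(float(h), df, p, mean_ranks, tie)


# ---------------------------------------------------------------------------
# Protected-area gap analysis
# ---------------------------------------------------------------------------

@dataclass
class GapResult:
    priority_area: float   # 10^4 km^2
    covered_area: float    # 10^4 km^2
    coverage_pct: float
    gap_pct: float


def coverage_from_areas(priority_area: float, covered_area: float) -> GapResult:
    """Coverage/gap percentages from priority and covered areas (10^4 km^2)."""
    if priority_area <= 0:
        raise ValueError("priority area must be > 0")
    if covered_area > priority_area + 1e-9:
        raise ValueError("covered area exceeds priority area")
    pct = 100.0 * covered_area / priority_area
    return GapResult(priority_area, covered_area, pct, 100.0 - pct)


def gap_analysis(current: ClassifiedRaster, protected) -> GapResult:
    """Protected-area coverage of the priority (moderate + high) habitat.

    A priority cell is covered iff its center falls inside any protected
    polygon; areas are geodesic.
    """
    priority = current.valid & (current.classes >= MODERATE)
    if not priority.any():
        raise ValueError("empty priority mask")
    areas = current.spec.cell_area_grid() / 1e4
    priority_area = float(areas[priority].sum())
    geoms = list(protected)
    if not geoms:
        return coverage_from_areas(priority_area, 0.0)
    merged = unary_union(geoms)
    rows, cols = np.nonzero(priority)
    lon, lat = current.spec.cell_center(rows, cols)
    inside = shapely.contains_xy(merged, lon, lat)
    covered_area = float(areas[rows[inside], cols[inside]].sum())
    return coverage_from_areas(priority_area, covered_area)


def scenario_gap_series(
    classified: dict[tuple[str, str], ClassifiedRaster],
    protected,
    scenarios: list[str],
    periods: list[str],
) -> pd.DataFrame:
    """Per-(scenario, period) priority area and protected coverage."""
    rows = []
    for scen in scenarios:
        for period in periods:
            res = gap_analysis(classified[(scen, period)], protected)
            rows.append(dict(scenario=scen, period=period,
                             priority_area=res.priority_area,
                             covered_area=res.covered_area,
                             coverage_pct=res.coverage_pct,
                             gap_pct=res.gap_pct))
    return pd.DataFrame(rows)
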
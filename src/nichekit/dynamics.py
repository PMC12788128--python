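"""Suitability classification and habitat-change indicators.

Continuous suitability p in [0, 1] is reclassified into four levels —
unsuitable (p < 0.1), poor (0.1 <= p < 0.3), moderate (0.3 <= p < 0.5) and
high (0.5 <= p <= 1.0) — and "suitable" for the change accounting is the
union of the three suitable levels (p >= 0.1).  Between two periods the
transition bookkeeping yields

    A_initial, A_final, A_expansion (unsuitable -> suitable),
    A_contraction (suitable -> unsuitable), A_stable (suitable -> suitable)

with geodesic cell areas on a sphere (R = 6371.0088 km), reported in
10^4 km^2, plus the full 4 x 4 class-flow matrix.  Four indicators summarize
a transition:

    RCR = (A_final - A_initial) / A_initial * 100      (relative change rate)
    CI  = (A_expansion + A_contraction) / A_initial * 100  (change intensity)
    SI  = A_stable / A_initial * 100                   (stability index)
    SDR = min(A_exp, A_con) / (A_exp + A_con)          (spatial displacement)

SDR ranges over [0, 0.5]: 0 means one-sided change, 0.5 a pure spatial swap.
Reported percentages are rounded half-away-from-zero to 2 decimals, and
period means average the rounded per-transition values (the convention used
in summary tables of this kind).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Raster, SuitabilityRaster, require_aligned

logger = logging.getLogger("nichekit")

#: Class codes.
UNSUITABLE, POOR, MODERATE, HIGH = 0, 1, 2, 3
CLASS_NAMES = {UNSUITABLE: "unsuitable", POOR: "poor", MODERATE: "moderate", HIGH: "high"}

#: Lower bounds of the poor/moderate/high classes on the logistic scale.
DEFAULT_THRESHOLDS = (0.1, 0.3, 0.5)


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals."""
    return float(np.sign(x) * np.floor(abs(x) * 100.0 + 0.5) / 100.0) + 0.0


@dataclass
class ClassifiedRaster:
    spec: object
    classes: np.ndarray        # int codes, nodata cells hold -1
    mask: np.ndarray
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def to_raster(self) -> Raster:
        vals = np.where(self.mask, self.spec.nodata, self.classes.astype(float))
        return Raster(self.spec, vals, self.mask)


def classify(p: SuitabilityRaster, thresholds=DEFAULT_THRESHOLDS) -> ClassifiedRaster:
    """Reclassify a suitability surface into the 4-level scheme.

    Boundary semantics: each class includes its lower bound and excludes its
    upper; the high class includes 1.0.
    """
    t1, t2, t3 = thresholds
    vals = p.values
    valid = p.valid
    if np.any((vals[valid] < 0) | (vals[valid] > 1)):
        raise ValueError("suitability values outside [0, 1]")
    cls = np.full(vals.shape, -1, dtype=int)
    v = vals[valid]
    c = np.zeros(v.shape, dtype=int)
    c[v >= t1] = POOR
    c[v >= t2] = MODERATE
    c[v >= t3] = HIGH
    cls[valid] = c
    return ClassifiedRaster(p.spec, cls, ~valid, thresholds)


def area_by_class(c: ClassifiedRaster) -> dict[int, float]:
    """Geodesic area per class in 10^4 km^2."""
    areas = c.spec.cell_area_grid()
    out = {}
    for code in (UNSUITABLE, POOR, MODERATE, HIGH):
        out[code] = float(areas[c.valid & (c.classes == code)].sum() / 1e4)
    return out


@dataclass
class TransitionSummary:
    """Area bookkeeping between two classified periods (10^4 km^2)."""

    a_initial: float
    a_final: float
    a_expansion: float
    a_contraction: float
    a_stable: float
    flow: pd.DataFrame | None = None  # 4x4 class-to-class areas

    def __post_init__(self) -> None:
        if abs(self.a_final - (self.a_initial + self.a_expansion - self.a_contraction)) > 1e-6:
            raise ValueError("transition areas do not balance")
        if abs((self.a_stable + self.a_contraction) - self.a_initial) > 1e-6:
            raise ValueError("A_stable + A_contraction must equal A_initial")


def transition_summary(c1: ClassifiedRaster, c2: ClassifiedRaster) -> TransitionSummary:
    """Account area flows between two periods.

    "Suitable" is binary (class >= poor).  The flow matrix holds all 16
    class-to-class areas; its marginals reconcile with per-period
    area_by_class.
    """
    if not c1.spec.aligned(c2.spec):
        raise ValueError("classified rasters are not aligned")
    if c1.thresholds != c2.thresholds:
        raise ValueError("classified rasters use different thresholds")
    areas = c1.spec.cell_area_grid() / 1e4
    valid = c1.valid & c2.valid
    s1 = valid & (c1.classes >= POOR)
    s2 = valid & (c2.classes >= POOR)
    a_initial = float(areas[s1].sum())
    a_final = float(areas[s2].sum())
    a_exp = float(areas[~s1 & s2 & valid].sum())
    a_con = float(areas[s1 & ~s2].sum())
    a_stable = float(areas[s1 & s2].sum())
    flow = pd.DataFrame(
        np.zeros((4, 4)),
        index=[CLASS_NAMES[i] for i in range(4)],
        columns=[CLASS_NAMES[i] for i in range(4)],
    )
    for i in range(4):
        for j in range(4):
            flow.iloc[i, j] = float(areas[valid & (c1.classes == i) & (c2.classes == j)].sum())
    return TransitionSummary(a_initial, a_final, a_exp, a_con, a_stable, flow)


def change_map(c1: ClassifiedRaster, c2: ClassifiedRaster) -> Raster:
    """Expansion/contraction/stable map coded 1 / -1 / 0 (binary suitable)."""
    if not c1.spec.aligned(c2.spec):
        raise ValueError("classified rasters are not aligned")
    valid = c1.valid & c2.valid
    s1 = c1.classes >= POOR
    s2 = c2.classes >= POOR
    out = np.zeros(s1.shape, dtype=float)
    out[~s1 & s2] = 1.0
    out[s1 & ~s2] = -1.0
    out[~valid] = c1.spec.nodata
    return Raster(c1.spec, out, ~valid)


@dataclass
class DynamicsIndicators:
    rcr: float   # %
    ci: float    # %
    si: float    # %
    sdr: float   # dimensionless, [0, 0.5]


def indicators(ts: TransitionSummary) -> DynamicsIndicators:
    """RCR/CI/SI/SDR for one transition (percentages to 2 decimals)."""
    if ts.a_initial <= 0:
        raise ValueError("indicators undefined for A_initial = 0")
    rcr = (ts.a_final - ts.a_initial) / ts.a_initial * 100.0
    ci = (ts.a_expansion + ts.a_contraction) / ts.a_initial * 100.0
    si = ts.a_stable / ts.a_initial * 100.0
    turnover = ts.a_expansion + ts.a_contraction
    sdr = min(ts.a_expansion, ts.a_contraction) / turnover if turnover > 0 else 0.0
    return DynamicsIndicators(round2(rcr), round2(ci), round2(si), round2(sdr))


def period_mean(values) -> float:
    """Mean of per-transition indicator values, each first rounded to 2 dp."""
    vals = [round2(v) for v in values]
    if not vals:
        raise ValueError("period_mean of empty sequence")
    return round2(float(np.mean(vals)))


def indicators_table(
    classified: dict[tuple[str, str], ClassifiedRaster],
    scenarios: list[str],
    periods: list[str],
) -> pd.DataFrame:
    """Per-scenario transition indicators plus a period-mean row each."""
    rows = []
    for scen in scenarios:
        per_scen = []
        seq = ["current"] + [p for p in periods if p != "current"]
        for p0, p1 in zip(seq[:-1], seq[1:]):
            ts = transition_summary(classified[(scen, p0)], classified[(scen, p1)])
            ind = indicators(ts)
            rows.append(dict(scenario=scen, transition=f"{p0}-{p1}",
                             rcr=ind.rcr, ci=ind.ci, si=ind.si, sdr=ind.sdr))
            per_scen.append(ind)
        rows.append(dict(
            scenario=scen, transition="period_mean",
            rcr=period_mean([i.rcr for i in per_scen]),
            ci=period_mean([i.ci for i in per_scen]),
            si=period_mean([i.si for i in per_scen]),
            sdr=period_mean([i.sdr for i in per_scen]),
        ))
    return pd.DataFrame(rows)
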
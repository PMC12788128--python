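"""Seeded synthetic inputs with known ground truth.

Every generator here is a pure function of its seed and parameters, so each
downstream stage (thinning, variable screening, model fitting, overlap,
dynamics, gap analysis) can be exercised against values known by
construction.  The default desk-scale grid is 100 x 120 cells at 0.05
degrees, roughly the ~5 km working resolution of gridded bioclimate data.

The random fields are low-pass-filtered white noise (Gaussian kernel,
sigma = 5 cells): smooth enough to look like interpolated climate surfaces
and simple enough that requested pairwise correlations can be imposed
exactly by empirical orthogonalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.special import expit
from shapely.geometry import box
from shapely.ops import unary_union

import pandas as pd

from .grids import EnvStack, GridSpec, OccurrenceSet, Raster, SuitabilityRaster

logger = logging.getLogger("nichekit")

#: Desk-scale default grid: 100 rows x 120 cols, 0.05 deg cells, SW China-ish.
DEFAULT_SPEC = GridSpec(ncols=120, nrows=100, xll=104.0, yll=25.0, cellsize=0.05)

#: Smoothing kernel width (cells) for the random fields.
FIELD_SMOOTH_SIGMA = 5.0

#: Suitable/unsuitable boundary used by the scenario constructor.
SUITABLE_CUT = 0.1


@dataclass(frozen=True)
class TruthModel:
    """Known species-environment relationship for simulation.

    Suitability is the inverse logit of a linear-quadratic score of
    standardized layer values:  s(z) = expit(b0 + sum_v a_v z_v + c_v z_v^2).
    Layers are standardized over valid cells so coefficients are on a
    comparable scale regardless of each variable's units.
    """

    coefficients: dict[str, tuple[float, float]]
    intercept: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not any(a != 0 or c != 0 for a, c in self.coefficients.values()):
            raise ValueError("TruthModel needs at least one nonzero weight")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def suitability(self, stack: EnvStack, seed: int | None = None) -> SuitabilityRaster:
        """Evaluate the truth over a stack; optional seeded logit-scale noise."""
        valid = stack.valid_mask()
        score = np.full(valid.shape, self.intercept, dtype=float)
        for name, (a, c) in self.coefficients.items():
            layer = stack[name]
            vals = layer.values
            mu = vals[valid].mean()
            sd = vals[valid].std()
            z = (vals - mu) / (sd if sd > 0 else 1.0)
            score += a * z + c * z**2
        if self.noise_sd > 0:
            rng = np.random.default_rng(seed)
            score = score + rng.normal(0.0, self.noise_sd, size=score.shape)
        p = expit(score)
        p[~valid] = stack.spec.nodata
        return Raster(stack.spec, p, ~valid)


# ---------------------------------------------------------------------------
# Environmental stacks
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Standardized low-pass-filtered white noise field."""
    f = gaussian_filter(rng.standard_normal(shape), FIELD_SMOOTH_SIGMA, mode="reflect")
    return (f - f.mean()) / f.std()


def _default_var_names(n: int) -> list[str]:
    names = [f"Bio{i}" for i in range(1, 20)]
    names += ["elevation", "slope", "aspect", "UVB1"]
    names += [f"soil_{i}" for i in range(1, 40)]
    return names[:n]


#: Plausible (offset, scale) per leading variable so layers have field-like units.
_VAR_RANGES = {
    "Bio1": (15.0, 5.0), "Bio2": (8.0, 2.0), "Bio6": (-2.0, 4.0),
    "Bio12": (1200.0, 400.0), "Bio14": (25.0, 12.0),
    "elevation": (1200.0, 600.0), "slope": (12.0, 6.0), "aspect": (180.0, 90.0),
    "UVB1": (4500.0, 800.0),
}


def make_env_stack(
    seed: int,
    spec: GridSpec = DEFAULT_SPEC,
    n_vars: int = 6,
    corr_pairs: list[tuple[int, int, float]] | None = None,
    names: list[str] | None = None,
) -> EnvStack:
    """Generate an aligned stack of smooth random environmental layers.

    ``corr_pairs`` lists (i, j, r) requests: layer j is rebuilt as an exact
    empirical mixture of layer i and an orthogonalized residual so the
    realized Pearson correlation over valid cells equals r (up to floating
    point).  A layer may appear as the second member of at most one pair.
    """
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    corr_pairs = corr_pairs or []
    targets: dict[int, tuple[int, float]] = {}
    for i, j, r in corr_pairs:
        if not (0 <= i < n_vars and 0 <= j < n_vars) or i == j:
            raise ValueError(f"invalid correlation pair ({i}, {j})")
        if abs(r) > 1:
            raise ValueError("|target r| must be <= 1")
        if j in targets or j in {p[0] for p in corr_pairs}:
            raise ValueError(f"contradictory correlation requests for layer {j}")
        targets[j] = (i, r)

    rng = np.random.default_rng(seed)
    shape = (spec.nrows, spec.ncols)
    fields = [_smooth_field(rng, shape) for _ in range(n_vars)]
    for j, (i, r) in targets.items():
        a, b = fields[i].ravel(), fields[j].ravel()
        # Orthogonalize b against a, renormalize, then mix to hit r exactly.
        resid = b - (a @ b / (a @ a)) * a
        resid_sd = resid.std()
        if resid_sd == 0:
            raise ValueError("degenerate field; cannot orthogonalize")
        resid = (resid - resid.mean()) / resid_sd
        mixed = r * a + np.sqrt(max(0.0, 1 - r * r)) * resid
        fields[j] = ((mixed - mixed.mean()) / mixed.std()).reshape(shape)

    names = names or _default_var_names(n_vars)
    layers: dict[str, Raster] = {}
    for name, f in zip(names, fields):
        offset, scale = _VAR_RANGES.get(name, (0.0, 1.0))
        layers[name] = Raster(spec, offset + scale * f, np.zeros(shape, dtype=bool))
    return EnvStack(spec, layers)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def sample_occurrences(
    truth: TruthModel,
    stack: EnvStack,
    n: int,
    duplicate_rate: float = 0.0,
    seed: int = 0,
    species: str = "synthetic",
) -> OccurrenceSet:
    """Draw occurrence points with cell probability proportional to suitability.

    A ``duplicate_rate`` fraction of the n points are re-draws inside
    already-sampled cells, jittered within the cell, so grid thinning (not
    coordinate de-duplication) is what removes them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= duplicate_rate < 1):
        raise ValueError("duplicate_rate must be in [0, 1)")
    valid = stack.valid_mask()
    if not valid.any():
        raise ValueError("all-nodata stack; cannot sample occurrences")
    suit = truth.suitability(stack)
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(valid)
    w = suit.values[valid]
    w = w / w.sum()
    n_dup = int(round(n * duplicate_rate))
    n_base = n - n_dup
    idx = rng.choice(len(rows), size=n_base, replace=True, p=w)
    if n_dup > 0:
        # Re-draws land uniformly among already-occupied cells.
        idx = np.concatenate([idx, rng.choice(idx, size=n_dup, replace=True)])
    spec = stack.spec
    jitter_x = rng.uniform(0.01, 0.99, size=n)
    jitter_y = rng.uniform(0.01, 0.99, size=n)
    lon = spec.xll + (cols[idx] + jitter_x) * spec.cellsize
    lat = spec.yll + (spec.nrows - rows[idx] - jitter_y) * spec.cellsize
    frame = pd.DataFrame({"species": species, "lon": lon, "lat": lat})
    return OccurrenceSet(frame)


# ---------------------------------------------------------------------------
# Multi-period scenario surfaces
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSet:
    """Suitability surfaces per (scenario, period) plus construction truth."""

    periods: list[str]
    scenarios: list[str]
    rasters: dict[tuple[str, str], SuitabilityRaster]
    #: (scenario, period) -> dict with planned expansion/contraction cell
    #: counts and their exact geodesic areas (10^4 km^2).
    truth: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        first = next(iter(self.rasters.values())).spec
        for r in self.rasters.values():
            if not r.spec.aligned(first):
                raise ValueError("scenario rasters are not aligned")


def make_scenario_set(
    base: SuitabilityRaster,
    plan: dict[tuple[str, str], tuple[int, int]],
    seed: int = 0,
    periods: list[str] | None = None,
) -> ScenarioSet:
    """Construct future surfaces realizing an exact expansion/contraction plan.

    ``plan`` maps (scenario, period) to (n_expansion_cells,
    n_contraction_cells) relative to the previous period of that scenario
    (the first listed period follows "current" = *base*).  Cells crossing
    the 0.1 boundary are chosen at the frontier of the suitable region
    (nearest by Euclidean distance transform, seeded tie-break), so
    A_expansion and A_contraction are known by construction.
    """
    scenarios = sorted({s for s, _ in plan})
    if periods is None:
        periods = list(dict.fromkeys(p for _, p in plan))
    rng = np.random.default_rng(seed)
    spec = base.spec
    area_grid = spec.cell_area_grid() / 1e4  # 10^4 km^2 per cell
    rasters: dict[tuple[str, str], SuitabilityRaster] = {}
    truth: dict[tuple[str, str], dict[str, float]] = {}
    for scen in scenarios:
        rasters[(scen, "current")] = base
        prev = base
        for period in periods:
            n_exp, n_con = plan.get((scen, period), (0, 0))
            vals = prev.values.copy()
            suitable = prev.valid & (vals >= SUITABLE_CUT)
            unsuitable = prev.valid & (vals < SUITABLE_CUT)

            def _frontier_pick(candidates: np.ndarray, other: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
                if k == 0:
                    return np.array([], dtype=int), np.array([], dtype=int)
                if candidates.sum() < k:
                    raise ValueError(
                        f"requested {k} cells but only {int(candidates.sum())} available"
                    )
                dist = distance_transform_edt(~other)
                rr, cc = np.nonzero(candidates)
                order = np.lexsort((rng.random(len(rr)), dist[rr, cc]))
                sel = order[:k]
                return rr[sel], cc[sel]

            er, ec = _frontier_pick(unsuitable, suitable, n_exp)
            cr, cc = _frontier_pick(suitable, unsuitable, n_con)
            vals[er, ec] = 0.15  # newly suitable (poor class)
            vals[cr, cc] = 0.05  # newly unsuitable
            new = Raster(spec, vals, prev.mask.copy())
            rasters[(scen, period)] = new
            truth[(scen, period)] = {
                "n_expansion": n_exp,
                "n_contraction": n_con,
                "area_expansion": float(area_grid[er, ec].sum()),
                "area_contraction": float(area_grid[cr, cc].sum()),
            }
            prev = new
    return ScenarioSet(periods=["current"] + periods, scenarios=scenarios,
                       rasters=rasters, truth=truth)


# ---------------------------------------------------------------------------
# Two-species niche clouds
# ---------------------------------------------------------------------------

def make_species_pair(
    separation: float,
    n_per_species: int,
    seed: int = 0,
    spec: GridSpec = DEFAULT_SPEC,
) -> tuple[OccurrenceSet, EnvStack]:
    """Two species whose environmental niches are bivariate normal clouds.

    The stack carries two linear gradient layers (env1 east-west, env2
    north-south) so a point's environmental values are a deterministic
    function of its location; species A and B are sampled from unit-SD
    normal clouds whose means are *separation* pooled SDs apart along env1.
    separation = 0 gives identical niches; large values give disjoint ones.
    """
    if n_per_species < 5:
        raise ValueError("n_per_species must be >= 5 (density estimation needs support)")
    rng = np.random.default_rng(seed)
    shape = (spec.nrows, spec.ncols)
    # env units: env1 spans [-8, 8] across the grid's width, env2 across height.
    col_centers = (np.arange(spec.ncols) + 0.5) / spec.ncols  # 0..1 west->east
    row_centers = (np.arange(spec.nrows) + 0.5) / spec.nrows  # 0..1 north->south
    env1 = np.tile(16.0 * (col_centers - 0.5), (spec.nrows, 1))
    env2 = np.tile(16.0 * (0.5 - row_centers)[:, None], (1, spec.ncols))
    stack = EnvStack(spec, {
        "env1": Raster(spec, env1, np.zeros(shape, bool)),
        "env2": Raster(spec, env2, np.zeros(shape, bool)),
    })

    def _draw(mean1: float, label: str) -> pd.DataFrame:
        e1 = np.clip(rng.normal(mean1, 1.0, n_per_species), -7.9, 7.9)
        e2 = np.clip(rng.normal(0.0, 1.0, n_per_species), -7.9, 7.9)
        # invert the gradients back to lon/lat
        fx = e1 / 16.0 + 0.5
        fy = 0.5 - e2 / 16.0
        lon = spec.xll + fx * spec.ncols * spec.cellsize
        lat = spec.yur - fy * spec.nrows * spec.cellsize
        return pd.DataFrame({"species": label, "lon": lon, "lat": lat})

    frame = pd.concat(
        [_draw(-separation / 2.0, "species_A"), _draw(separation / 2.0, "species_B")],
        ignore_index=True,
    )
    return OccurrenceSet(frame), stack


# ---------------------------------------------------------------------------
# Protected-area polygons
# ---------------------------------------------------------------------------

def make_protected_polygons(
    spec: GridSpec,
    priority_mask: Raster,
    coverage_target: float,
    seed: int = 0,
):
    """Polygons covering a seeded subset of priority cells.

    The realized covered-area fraction is within one cell-area of
    ``coverage_target`` because whole cells are added greedily (in seeded
    random order) until the target is reached.
    """
    if not (0.0 <= coverage_target <= 1.0):
        raise ValueError("coverage_target must be in [0, 1]")
    mask = priority_mask.valid & (priority_mask.values > 0)
    rows, cols = np.nonzero(mask)
    if coverage_target == 0.0 or len(rows) == 0:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    areas = spec.cell_area_grid()
    total = areas[rows, cols].sum()
    cum = 0.0
    boxes = []
    for k in order:
        r, c = rows[k], cols[k]
        west = spec.xll + c * spec.cellsize
        south = spec.yll + (spec.nrows - r - 1) * spec.cellsize
        boxes.append(box(west, south, west + spec.cellsize, south + spec.cellsize))
        cum += areas[r, c]
        if cum >= coverage_target * total - 1e-12:
            break
    merged = unary_union(boxes)
    return [merged]
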
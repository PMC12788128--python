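"""Niche-overlap quantification in environmental space.

Occurrence-point environmental values are projected into a shared two-axis
principal-component space; each species' occupancy of that space is
summarized by a normalized kernel-density surface on a common 35 x 35 grid,
and pairwise overlap is Schoener's D:

    D = 1 - 1/2 * sum_i |p_x,i - p_y,i|

with p the normalized densities.  D = 0 means disjoint niches, D = 1
identical niches.  A fixed 35 x 35 grid keeps density estimates stable even
for very small samples while not washing out fine structure.

Genus-vs-species prediction consistency is measured on suitability rasters:
the cell-wise maximum composite of the species maps, the Pearson correlation
over jointly valid cells, and the Jaccard overlap of high-suitability
(p >= 0.5) areas.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .envselect import VariableTable
from .grids import Raster, SuitabilityRaster, require_aligned

logger = logging.getLogger("nichekit")

GRID_N = 35            # density grid is GRID_N x GRID_N
EXTENT_MARGIN = 0.10   # fractional margin added to the pooled score range
HIGH_CUT = 0.5         # high-suitability threshold for the overlap ratio


@dataclass
class NichePCA:
    """Two-component PCA of standardized environmental values."""

    loadings: np.ndarray           # 2 x n_vars
    means: np.ndarray
    scales: np.ndarray
    explained: tuple[float, float]
    variables: list[str]

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        z = (frame[self.variables].to_numpy(float) - self.means) / self.scales
        return z @ self.loadings.T


def fit_pca(table: VariableTable) -> NichePCA:
    """Fit the shared environmental PCA (z-scored variables, 2 components).

    Sign convention: each component's largest-magnitude loading is positive,
    so the axes are deterministic across runs.
    """
    frame = table.frame
    if len(frame) < 3:
        raise ValueError("fit_pca needs at least 3 rows")
    if frame.shape[1] < 2:
        raise ValueError("fit_pca needs at least 2 variables")
    x = frame.to_numpy(float)
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    z = (x - means) / scales
    if np.linalg.matrix_rank(z - z.mean(axis=0)) < 1:
        raise ValueError("environmental table is degenerate (zero variance)")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.copy()
    for i in range(2):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    expl = pca.explained_variance_ratio_
    return NichePCA(loadings, means, scales, (float(expl[0]), float(expl[1])),
                    list(frame.columns))


@dataclass
class NicheDensityGrid:
    """Normalized 35 x 35 occurrence density in (PC1, PC2) space."""

    grid: np.ndarray
    extent: tuple[tuple[float, float], tuple[float, float]]
    species: str = ""

    @property
    def n(self) -> int:
        return self.grid.size

    def __post_init__(self) -> None:
        total = self.grid.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("density grid must sum to 1")


def pooled_extent(scores_by_species: dict[str, np.ndarray],
                  margin: float = EXTENT_MARGIN):
    """Pooled (PC1, PC2) range across species plus a fractional margin."""
    allpts = np.vstack(list(scores_by_species.values()))
    mins = allpts.min(axis=0)
    maxs = allpts.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    mins = mins - margin * span
    maxs = maxs + margin * span
    return ((float(mins[0]), float(maxs[0])), (float(mins[1]), float(maxs[1])))


def density_grid(
    scores: np.ndarray,
    extent,
    species: str = "",
    grid_n: int = GRID_N,
) -> NicheDensityGrid:
    """Gaussian KDE evaluated at the grid cell centers, renormalized to sum 1.

    The bandwidth is the per-axis normal-reference rule h = sigma * n^(-1/6)
    (two-dimensional Silverman); a zero-variance axis is floored at 1% of
    the extent with a warning.
    """
    scores = np.asarray(scores, float)
    if scores.shape[0] < 5:
        raise ValueError("density_grid needs at least 5 points")
    (x0, x1), (y0, y1) = extent
    n = scores.shape[0]
    bw = []
    for axis, (lo, hi) in zip(range(2), ((x0, x1), (y0, y1))):
        sd = scores[:, axis].std()
        h = sd * n ** (-1.0 / 6.0)
        floor = 0.01 * (hi - lo)
        if h <= 0:
            logger.warning("density_grid: zero-variance axis %d; bandwidth floored", axis)
            h = floor
        bw.append(max(h, 1e-12))
    cx = x0 + (np.arange(grid_n) + 0.5) * (x1 - x0) / grid_n
    cy = y0 + (np.arange(grid_n) + 0.5) * (y1 - y0) / grid_n
    # product Gaussian kernel, evaluated separably then combined
    kx = np.exp(-0.5 * ((cx[None, :] - scores[:, 0, None]) / bw[0]) ** 2)
    ky = np.exp(-0.5 * ((cy[None, :] - scores[:, 1, None]) / bw[1]) ** 2)
    dens = ky.T @ kx  # rows = PC2 axis, cols = PC1 axis
    total = dens.sum()
    if total <= 0:
        raise ValueError("all density mass fell off the grid")
    return NicheDensityGrid(dens / total, extent, species)


def schoeners_d(p: NicheDensityGrid, q: NicheDensityGrid) -> float:
    """Schoener's D = 1 - 1/2 sum |p_i - q_i| over the shared grid."""
    if p.grid.shape != q.grid.shape or p.extent != q.extent:
        raise ValueError("density grids have mismatched shape or extent")
    d = 1.0 - 0.5 * np.abs(p.grid - q.grid).sum()
    return float(min(max(d, 0.0), 1.0))


@dataclass
class OverlapMatrix:
    matrix: pd.DataFrame
    n_zero_pairs: int
    n_pairs: int

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("overlap matrix must be symmetric")


def overlap_matrix(
    species_tables: dict[str, VariableTable],
    mode: str = "pca",
    zero_tol: float = 1e-4,
) -> OverlapMatrix:
    """All pairwise Schoener's D values on one shared space.

    mode 'pca' (default): one PCA fitted on the pooled occurrence points of
    all species, densities on the shared 2-D grid.  mode 'gradient': D is
    computed per environmental variable on 1-D density grids and aggregated
    by the maximum over variables (an alternative reading of "overlap along
    environmental gradients").
    Species with fewer than 5 points are excluded with a warning.
    """
    usable = {}
    for sp, tab in species_tables.items():
        if len(tab) < 5:
            logger.warning("overlap_matrix: species %s has < 5 points; excluded", sp)
        else:
            usable[sp] = tab
    if len(usable) < 2:
        raise ValueError("need at least 2 species with >= 5 points")
    names = list(usable)

    grids: dict[str, NicheDensityGrid] | None = None
    if mode == "pca":
        pooled = VariableTable(pd.concat([t.frame for t in usable.values()], ignore_index=True))
        pca = fit_pca(pooled)
        scores = {sp: pca.transform(t.frame) for sp, t in usable.items()}
        extent = pooled_extent(scores)
        grids = {sp: density_grid(s, extent, sp) for sp, s in scores.items()}
        dfun = lambda a, b: schoeners_d(grids[a], grids[b])
    elif mode == "gradient":
        variables = usable[names[0]].variables
        grids_1d: dict[tuple[str, str], np.ndarray] = {}
        for v in variables:
            lo = min(t.frame[v].min() for t in usable.values())
            hi = max(t.frame[v].max() for t in usable.values())
            span = (hi - lo) if hi > lo else 1.0
            lo, hi = lo - EXTENT_MARGIN * span, hi + EXTENT_MARGIN * span
            centers = lo + (np.arange(GRID_N) + 0.5) * (hi - lo) / GRID_N
            for sp, t in usable.items():
                x = t.frame[v].to_numpy(float)
                h = max(x.std() * len(x) ** (-1 / 5.0), 0.01 * (hi - lo), 1e-12)
                dens = np.exp(-0.5 * ((centers[None, :] - x[:, None]) / h) ** 2).sum(axis=0)
                grids_1d[(sp, v)] = dens / dens.sum()

        def dfun(a, b):
            return max(
                float(1.0 - 0.5 * np.abs(grids_1d[(a, v)] - grids_1d[(b, v)]).sum())
                for v in variables
            )
    else:
        raise ValueError("mode must be 'pca' or 'gradient'")

    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    n_zero = 0
    for a, b in itertools.combinations(names, 2):
        d = dfun(a, b)
        mat.loc[a, b] = mat.loc[b, a] = d
        if d <= zero_tol:
            n_zero += 1
    n_pairs = len(names) * (len(names) - 1) // 2
    return OverlapMatrix(mat, n_zero, n_pairs)


# ---------------------------------------------------------------------------
# Genus-vs-species geographic consistency
# ---------------------------------------------------------------------------

def composite_max(species_rasters: list[SuitabilityRaster]) -> SuitabilityRaster:
    """Cell-wise maximum of the species suitability maps."""
    if not species_rasters:
        raise ValueError("no rasters")
    require_aligned(*species_rasters)
    vals = np.max([r.values for r in species_rasters], axis=0)
    mask = species_rasters[0].mask.copy()
    for r in species_rasters[1:]:
        mask |= r.mask
    vals = np.where(mask, species_rasters[0].spec.nodata, vals)
    return Raster(species_rasters[0].spec, vals, mask)


def consistency_metrics(
    genus: SuitabilityRaster,
    composite: SuitabilityRaster,
    high_cut: float = HIGH_CUT,
) -> tuple[float, float]:
    """(Pearson r, high-suitability Jaccard overlap %) between two maps.

    The overlap ratio is 100 * area(both >= cut) / area(either >= cut) with
    geodesic cell areas.  Raises if no cell reaches the cut in either map.
    """
    require_aligned(genus, composite)
    valid = genus.valid & composite.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 jointly valid cells")
    a = genus.values[valid]
    b = composite.values[valid]
    if a.std() == 0 or b.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    areas = genus.spec.cell_area_grid()
    ha = valid & (genus.values >= high_cut)
    hb = valid & (composite.values >= high_cut)
    union = areas[ha | hb].sum()
    if union == 0:
        raise ValueError("no cell reaches the high-suitability cut in either raster")
    ratio = 100.0 * areas[ha & hb].sum() / union
    return r, float(ratio)
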
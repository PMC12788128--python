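import numpy as np
import pandas as pd
import pytest

from nichekit import synth
from nichekit.envselect import VariableTable, extract_at_points
from nichekit.grids import GridSpec, Raster
from nichekit.overlap import (
    GRID_N,
    NicheDensityGrid,
    composite_max,
    consistency_metrics,
    density_grid,
    fit_pca,
    overlap_matrix,
    pooled_extent,
    schoeners_d,
)


def _vt(data):
    return VariableTable(pd.DataFrame(data))


class TestPca:
    def test_perfectly_correlated_pair_loads_on_pc1(self, rng):
        x = rng.normal(size=200)
        pca = fit_pca(_vt({"a": x, "b": 2 * x + 3}))
        assert pca.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_data_splits_variance(self, rng):
        z = rng.normal(size=(20000, 2))
        pca = fit_pca(_vt({"a": z[:, 0], "b": z[:, 1]}))
        assert pca.explained[0] == pytest.approx(0.5, abs=0.02)
        assert pca.explained[1] == pytest.approx(0.5, abs=0.02)

    def test_transform_preserves_norm_in_full_rank_2d(self, rng):
        z = rng.normal(size=(100, 2))
        frame = pd.DataFrame({"a": z[:, 0], "b": z[:, 1]})
        pca = fit_pca(_vt(frame))
        scores = pca.transform(frame)
        standardized = (frame.to_numpy() - pca.means) / pca.scales
        # orthonormal loadings: projecting then back-projecting is identity
        np.testing.assert_allclose(scores @ pca.loadings, standardized, atol=1e-9)

    def test_sign_convention_deterministic(self, rng):
        z = rng.normal(size=(300, 3))
        frame = pd.DataFrame({"a": z[:, 0], "b": z[:, 1], "c": z[:, 2]})
        l1 = fit_pca(_vt(frame)).loadings
        l2 = fit_pca(_vt(frame.copy())).loadings
        np.testing.assert_array_equal(l1, l2)
        for comp in l1:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(_vt({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}))


class TestDensityGrid:
    def test_sums_to_one(self, rng):
        scores = rng.normal(size=(100, 2))
        g = density_grid(scores, ((-4, 4), (-4, 4)))
        assert g.grid.sum() == pytest.approx(1.0, abs=1e-12)
        assert g.n == GRID_N * GRID_N

    def test_point_mass_concentrates(self):
        scores = np.zeros((10, 2))  # zero variance -> floored bandwidth
        g = density_grid(scores, ((-1, 1), (-1, 1)))
        # nearly all mass in the single cell containing the points
        assert g.grid.max() >= 0.9
        ci = np.unravel_index(np.argmax(g.grid), g.grid.shape)
        assert ci == (GRID_N // 2, GRID_N // 2)

    def test_mode_matches_fine_grid_brute_force(self, rng):
        scores = rng.normal(loc=[0.5, -0.3], scale=0.5, size=(200, 2))
        extent = ((-3, 3), (-3, 3))
        g = density_grid(scores, extent)
        ci = np.unravel_index(np.argmax(g.grid), g.grid.shape)
        coarse_step = 6.0 / GRID_N
        mode_x = extent[0][0] + (ci[1] + 0.5) * coarse_step
        mode_y = extent[1][0] + (ci[0] + 0.5) * coarse_step
        # brute-force KDE on a 10x finer grid with the same bandwidths
        n = len(scores)
        bw = [scores[:, k].std() * n ** (-1 / 6) for k in range(2)]
        fine = GRID_N * 10
        fx = extent[0][0] + (np.arange(fine) + 0.5) * 6.0 / fine
        fy = extent[1][0] + (np.arange(fine) + 0.5) * 6.0 / fine
        dens = np.zeros((fine, fine))
        for p in scores:
            dens += np.exp(-0.5 * ((fy[:, None] - p[1]) / bw[1]) ** 2) * np.exp(
                -0.5 * ((fx[None, :] - p[0]) / bw[0]) ** 2
            )
        fi = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(fx[fi[1]] - mode_x) <= coarse_step
        assert abs(fy[fi[0]] - mode_y) <= coarse_step

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            density_grid(np.zeros((4, 2)), ((-1, 1), (-1, 1)))


class TestSchoenersD:
    def test_identical_grids_give_one(self, rng):
        g = density_grid(rng.normal(size=(50, 2)), ((-4, 4), (-4, 4)))
        assert schoeners_d(g, g) == 1.0

    def test_disjoint_supports_give_zero(self):
        extent = ((0, 1), (0, 1))
        a = np.zeros((GRID_N, GRID_N))
        b = np.zeros((GRID_N, GRID_N))
        a[0, 0] = 1.0
        b[-1, -1] = 1.0
        pa = NicheDensityGrid(a, extent)
        pb = NicheDensityGrid(b, extent)
        assert schoeners_d(pa, pb) == 0.0

    def test_uniform_vs_point_mass_closed_form(self):
        extent = ((0, 1), (0, 1))
        G = GRID_N * GRID_N
        uniform = NicheDensityGrid(np.full((GRID_N, GRID_N), 1.0 / G), extent)
        point = np.zeros((GRID_N, GRID_N))
        point[3, 5] = 1.0
        assert schoeners_d(uniform, NicheDensityGrid(point, extent)) == pytest.approx(
            1.0 / G, abs=1e-12
        )

    def test_matches_elementwise_oracle_and_symmetry(self, rng):
        extent = ((0, 1), (0, 1))
        for _ in range(10):
            a = rng.random((GRID_N, GRID_N))
            b = rng.random((GRID_N, GRID_N))
            a /= a.sum()
            b /= b.sum()
            pa, pb = NicheDensityGrid(a, extent), NicheDensityGrid(b, extent)
            oracle = 1.0 - 0.5 * sum(
                abs(a[i, j] - b[i, j]) for i in range(GRID_N) for j in range(GRID_N)
            )
            assert schoeners_d(pa, pb) == pytest.approx(oracle, abs=1e-12)
            assert schoeners_d(pa, pb) == schoeners_d(pb, pa)
            assert 0.0 <= schoeners_d(pa, pb) <= 1.0


class TestOverlapMatrix:
    def _tables(self, occ, stack):
        return {sp: extract_at_points(stack, occ.for_species(sp)) for sp in occ.species}

    def test_identical_niches_give_high_d(self):
        occ, stack = synth.make_species_pair(0.0, 500, seed=21)
        om = overlap_matrix(self._tables(occ, stack))
        assert om.matrix.iloc[0, 1] >= 0.85

    def test_disjoint_niches_give_low_d(self):
        occ, stack = synth.make_species_pair(10.0, 500, seed=21)
        om = overlap_matrix(self._tables(occ, stack))
        assert om.matrix.iloc[0, 1] <= 0.05

    def test_d_symmetric_in_species_order(self):
        occ, stack = synth.make_species_pair(2.0, 100, seed=5)
        om = overlap_matrix(self._tables(occ, stack))
        assert om.matrix.iloc[0, 1] == om.matrix.iloc[1, 0]

    def test_d_decreases_with_separation_on_average(self):
        means = []
        for sep in (0.0, 3.0, 6.0):
            ds = []
            for seed in (1, 2, 3):
                occ, stack = synth.make_species_pair(sep, 200, seed=seed)
                om = overlap_matrix(self._tables(occ, stack))
                ds.append(om.matrix.iloc[0, 1])
            means.append(np.mean(ds))
        assert means[0] > means[1] > means[2]

    def test_seven_species_yield_21_pairs(self, rng):
        tables = {}
        for i in range(7):
            z = rng.normal(loc=3.0 * i, size=(30, 2))
            tables[f"sp{i}"] = _vt({"a": z[:, 0], "b": z[:, 1]})
        om = overlap_matrix(tables)
        assert om.n_pairs == 21
        m = om.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T, atol=1e-12)

    def test_duplicated_species_table_gives_d_one(self, rng):
        z = rng.normal(size=(40, 2))
        t = _vt({"a": z[:, 0], "b": z[:, 1]})
        om = overlap_matrix({"x": t, "y": _vt(t.frame.copy())})
        assert om.matrix.loc["x", "y"] == pytest.approx(1.0, abs=1e-12)

    def test_gradient_mode_runs_and_is_symmetric(self):
        occ, stack = synth.make_species_pair(4.0, 100, seed=3)
        om = overlap_matrix(self._tables(occ, stack), mode="gradient")
        assert om.matrix.iloc[0, 1] == om.matrix.iloc[1, 0]
        assert 0.0 <= om.matrix.iloc[0, 1] <= 1.0

    def test_small_species_excluded(self, rng):
        z = rng.normal(size=(30, 2))
        tables = {
            "big": _vt({"a": z[:, 0], "b": z[:, 1]}),
            "big2": _vt({"a": z[:, 0] + 1, "b": z[:, 1]}),
            "tiny": _vt({"a": z[:3, 0], "b": z[:3, 1]}),
        }
        om = overlap_matrix(tables)
        assert "tiny" not in om.matrix.index


class TestComposite:
    def _raster(self, spec, vals):
        return Raster(spec, np.asarray(vals, float), np.zeros_like(np.asarray(vals), dtype=bool))

    def test_single_input_identity_and_pairwise_max(self, small_spec):
        rng = np.random.default_rng(0)
        a = self._raster(small_spec, rng.random((small_spec.nrows, small_spec.ncols)))
        b = self._raster(small_spec, rng.random((small_spec.nrows, small_spec.ncols)))
        np.testing.assert_array_equal(composite_max([a]).values, a.values)
        comp = composite_max([a, b])
        np.testing.assert_array_equal(comp.values, np.maximum(a.values, b.values))
        assert (comp.values >= a.values).all() and (comp.values >= b.values).all()

    def test_misaligned_inputs_rejected(self, small_spec):
        other = GridSpec(small_spec.ncols, small_spec.nrows, small_spec.xll + 0.5,
                         small_spec.yll, small_spec.cellsize)
        a = self._raster(small_spec, np.zeros((small_spec.nrows, small_spec.ncols)))
        b = self._raster(other, np.zeros((small_spec.nrows, small_spec.ncols)))
        with pytest.raises(ValueError):
            composite_max([a, b])


class TestConsistency:
    def _raster(self, spec, vals):
        return Raster(spec, vals, np.zeros_like(vals, dtype=bool))

    def test_identical_maps(self, small_spec, rng):
        vals = rng.random((small_spec.nrows, small_spec.ncols))
        r = self._raster(small_spec, vals)
        pear, ratio = consistency_metrics(r, self._raster(small_spec, vals.copy()))
        assert pear == pytest.approx(1.0)
        assert ratio == pytest.approx(100.0)

    def test_disjoint_high_masks_give_zero_ratio(self, small_spec):
        a = np.full((small_spec.nrows, small_spec.ncols), 0.1)
        b = a.copy()
        a[0, 0] = 0.9
        b[5, 5] = 0.9
        _, ratio = consistency_metrics(self._raster(small_spec, a), self._raster(small_spec, b))
        assert ratio == 0.0

    def test_pearson_matches_textbook_formula(self, small_spec, rng):
        a = rng.random((small_spec.nrows, small_spec.ncols))
        b = rng.random((small_spec.nrows, small_spec.ncols)) + 0.3 * a
        b = b / b.max()
        pear, _ = consistency_metrics(self._raster(small_spec, a), self._raster(small_spec, b))
        x, y = a.ravel(), b.ravel()
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pear == pytest.approx(oracle, abs=1e-12)
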
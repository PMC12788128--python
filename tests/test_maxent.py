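import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from nichekit import maxent
from nichekit.maxent import (
    FeatureSpec,
    aicc,
    auc,
    fit_from_tables,
    fit_maxent,
    jackknife_gains,
    percent_contribution,
    predict,
    replicate_scheme,
    response_curves,
    tune,
)


def gibbs_presences(rng, background, lam_true, var="x1", m=500):
    w = np.exp(lam_true * background[var].to_numpy())
    w = w / w.sum()
    idx = rng.choice(len(background), size=m, p=w)
    return background.iloc[idx].reset_index(drop=True)


class TestFeatures:
    def test_linear_is_minmax_scaling(self, uniform_background):
        spec = FeatureSpec.from_background("L", uniform_background[["x1"]])
        X = spec.build(uniform_background[["x1"]])
        lo, hi = spec.normalizers["x1"]
        expected = (uniform_background["x1"].to_numpy() - lo) / (hi - lo)
        np.testing.assert_allclose(X[:, 0], expected)
        assert X.min() == 0.0 and X.max() == 1.0

    @pytest.mark.parametrize(
        "classes,knots,expected",
        [("LQ", 5, 4), ("LQPH", 5, 25), ("L", 5, 2), ("LQPHT", 4, 2 + 2 + 1 + 16 + 8)],
    )
    def test_column_counts(self, uniform_background, classes, knots, expected):
        spec = FeatureSpec.from_background(classes, uniform_background, hinge_knots=knots)
        assert spec.build(uniform_background).shape[1] == expected

    def test_constant_variable_drops_derived_features(self, uniform_background):
        frame = uniform_background.copy()
        frame["flat"] = 1.0
        spec = FeatureSpec.from_background("LQ", frame)
        # flat keeps its L column (all zeros) but contributes no Q
        assert spec.build(frame).shape[1] == 3 + 2

    def test_invalid_class_combinations(self, uniform_background):
        with pytest.raises(ValueError):
            FeatureSpec.from_background("Q", uniform_background)


class TestFit:
    def test_huge_penalty_gives_uniform_model(self, uniform_background, rng):
        pres = uniform_background.iloc[:50]
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=1e6)
        assert np.all(model.lambdas == 0.0)
        assert model.training_gain == 0.0
        assert model.entropy_H == pytest.approx(np.log(len(uniform_background)))
        np.testing.assert_allclose(
            model.logistic(uniform_background.iloc[:5]), 0.5, atol=1e-12
        )

    def test_null_presences_give_negligible_gain(self, uniform_background, rng):
        pres = uniform_background.sample(500, random_state=1)
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=1.0)
        assert model.training_gain <= 0.05

    def test_gain_non_decreasing_each_sweep(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.0, m=200)
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=0.5)
        assert np.all(np.diff(model.gain_trace) >= -1e-9)

    def test_recovers_known_gibbs_coefficient(self, uniform_background, rng):
        # independent oracle: 1-D grid search of the unpenalized likelihood
        lam_true = 2.0
        pres = gibbs_presences(rng, uniform_background, lam_true, m=2000)
        model = fit_from_tables(pres[["x1"]], uniform_background[["x1"]],
                                classes="L", rm=0.01)
        spec = model.feature_spec
        Xp = spec.build(pres[["x1"]])[:, 0]
        Xb = spec.build(uniform_background[["x1"]])[:, 0]
        grid = np.linspace(0.0, 4.0, 801)
        gains = [g * Xp.mean() - (logsumexp(g * Xb) - np.log(Xb.size)) for g in grid]
        lam_oracle = grid[int(np.argmax(gains))]
        assert model.lambdas[0] == pytest.approx(lam_oracle, abs=0.05)
        # both within 10% of the generating coefficient (features are scaled
        # copies of x1 here, so the scales match)
        assert abs(model.lambdas[0] - lam_true) / lam_true <= 0.10

    def test_l1_norm_shrinks_monotonically_with_rm(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.5, m=300)
        norms = []
        for rm in (1.0, 10.0, 100.0, 1e4):
            model = fit_from_tables(pres, uniform_background, classes="LQ", rm=rm)
            norms.append(np.abs(model.lambdas).sum())
        assert all(a >= b - 1e-12 for a, b in zip(norms[:-1], norms[1:]))
        assert norms[-1] == 0.0

    def test_raw_normalizes_over_background(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 1.5, m=200)
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=1.0)
        assert model.raw(uniform_background).sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonfinite_features_rejected(self, uniform_background):
        X = np.ones((10, 1))
        Xb = np.ones((200, 1))
        Xb[0, 0] = np.nan
        spec = FeatureSpec.from_background("L", uniform_background[["x1"]])
        with pytest.raises(ValueError, match="finite"):
            fit_maxent(X, Xb, spec.columns()[:1], rm=1.0)


class TestPredict:
    def test_logistic_monotone_in_raw(self, env_stack, rng):
        import nichekit.envselect as es
        from nichekit import synth
        truth = synth.TruthModel({"Bio1": (1.5, -1.0)})
        occ = synth.sample_occurrences(truth, env_stack, 150, seed=3)
        pres = es.extract_at_points(env_stack, occ).frame
        valid = env_stack.valid_mask()
        rows, cols = np.nonzero(valid)
        pick = rng.choice(len(rows), 800, replace=False)
        bg = pd.DataFrame({n: env_stack[n].values[rows[pick], cols[pick]] for n in env_stack.names})
        model = fit_from_tables(pres, bg, classes="LQ", rm=1.0)
        raw = predict(model, env_stack, "raw").valid_values()
        logi = predict(model, env_stack, "logistic").valid_values()
        assert np.all((logi > 0) & (logi < 1))
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(logi))

    def test_missing_variable_named(self, uniform_background):
        from nichekit.grids import EnvStack, GridSpec, Raster
        pres = uniform_background.iloc[:30]
        model = fit_from_tables(pres, uniform_background, classes="L", rm=1.0)
        spec = GridSpec(ncols=3, nrows=3, xll=0.0, yll=0.0, cellsize=1.0)
        stack = EnvStack(spec, {"x1": Raster(spec, np.zeros((3, 3)))})
        with pytest.raises(KeyError, match="x2"):
            predict(model, stack)


class TestAuc:
    def test_separable_and_identical(self):
        val, label = auc([3.0, 4.0], [1.0, 2.0])
        assert val == 1.0 and label == "high performance"
        val, _ = auc([1.0, 2.0], [1.0, 2.0])
        assert val == 0.5

    def test_band_labels(self):
        scores = np.linspace(0, 1, 1000)
        # construct a score set with AUC exactly 0.918 via rank placement
        assert auc([10.0], [1.0])[1] == "high performance"
        assert auc([1.0], [1.0])[0] == 0.5

    def test_matches_trapezoidal_roc_oracle(self, rng):
        sp = rng.normal(1.0, 1.0, 200)
        sb = rng.normal(0.0, 1.0, 400)
        val, _ = auc(sp, sb)
        thr = np.unique(np.concatenate([sp, sb]))
        tpr = [(sp >= t).mean() for t in thr[::-1]]
        fpr = [(sb >= t).mean() for t in thr[::-1]]
        oracle = np.trapezoid([0] + tpr + [1], [0] + fpr + [1])
        assert val == pytest.approx(oracle, abs=1e-9)


class TestAicc:
    def test_uniform_model_closed_form(self, uniform_background):
        pres = uniform_background.iloc[:40]
        model = fit_from_tables(pres, uniform_background, classes="L", rm=1e6)
        spec = model.feature_spec
        k, lnL, value, valid = aicc(model, spec.build(pres), spec.build(uniform_background))
        n, N = len(pres), len(uniform_background)
        assert k == 0 and valid
        assert lnL == pytest.approx(-n * np.log(N), rel=1e-12)
        assert value == pytest.approx(2 * n * np.log(N), rel=1e-12)

    def test_formula_matches_hand_computation(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.0, m=60)
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=0.5)
        spec = model.feature_spec
        Xo, Xa = spec.build(pres), spec.build(uniform_background)
        k, lnL, value, valid = aicc(model, Xo, Xa)
        assert valid
        expected = 2 * k - 2 * lnL + 2 * k * (k + 1) / (len(pres) - k - 1)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_overparameterized_flagged_invalid(self, uniform_background):
        pres = uniform_background.iloc[:3]
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=1e-4)
        spec = model.feature_spec
        Xo, Xa = spec.build(pres), spec.build(uniform_background)
        k, lnL, value, valid = aicc(model, Xo, Xa)
        if k >= len(pres) - 1:
            assert not valid and np.isnan(value)


class TestTune:
    def test_default_grid_enumerates_48_and_selects_delta_zero(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.0, m=60)
        res = tune(pres, uniform_background, hinge_knots=4, seed=0, max_sweeps=60)
        assert len(res.table) == 48
        sel = res.table[(res.table.fc == res.selected["fc"]) & (res.table.rm == res.selected["rm"])]
        assert sel["delta_aicc"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert (res.table["delta_aicc"].dropna() >= -1e-9).all()

    def test_aicc_tie_broken_by_test_auc(self):
        table = pd.DataFrame(
            dict(fc=["L", "LQ"], rm=[1.0, 1.0], k=[2, 2], lnL=[-5.0, -5.0],
                 aicc=[10.0, 10.0], train_auc=[0.8, 0.8], test_auc=[0.7, 0.9],
                 valid=[True, True])
        )
        # replicate the selection rule on a crafted tie
        table["delta_aicc"] = table["aicc"] - table["aicc"].min()
        cand = table[table["valid"] & (table["delta_aicc"] <= 1e-9)].copy()
        cand = cand.sort_values(by=["test_auc", "k", "fc"], ascending=[False, True, True])
        assert cand.iloc[0]["fc"] == "LQ"


class TestImportance:
    def test_jackknife_gain_structure(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.5, m=300)
        table = jackknife_gains(pres, uniform_background, classes="L", rm=0.5)
        gains = table.set_index("variable")
        # x2 is pure noise; x1 carries all signal
        assert gains.loc["x2", "gain_only"] <= 0.05
        assert gains.loc["x1", "gain_only"] == pytest.approx(gains.loc["x1", "gain_full"], abs=0.05)
        assert (table["gain_without"] <= table["gain_full"] + 1e-6).all()

    def test_percent_contribution_single_variable(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.0, m=200)
        model = fit_from_tables(pres[["x1"]], uniform_background[["x1"]], classes="LQ", rm=0.5)
        contrib = percent_contribution(model)
        assert contrib["x1"] == pytest.approx(100.0)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_variable_shares_credit(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.0, m=300)
        dup_bg = uniform_background[["x1"]].copy()
        dup_bg["x1_copy"] = dup_bg["x1"]
        dup_pres = pres[["x1"]].copy()
        dup_pres["x1_copy"] = dup_pres["x1"]
        model = fit_from_tables(dup_pres, dup_bg, classes="L", rm=0.5)
        contrib = percent_contribution(model)
        assert contrib["x1"] + contrib["x1_copy"] == pytest.approx(100.0, abs=1e-6)


class TestResponseCurves:
    def test_only_mode_recovers_quadratic_peak(self, uniform_background, rng):
        # quadratic Gibbs truth peaked at x* = 0.6
        x = uniform_background["x1"].to_numpy()
        s = -8.0 * (x - 0.6) ** 2
        w = np.exp(s) / np.exp(s).sum()
        idx = rng.choice(len(x), 1000, p=w)
        pres = uniform_background.iloc[idx].reset_index(drop=True)
        model = fit_from_tables(pres, uniform_background, classes="LQ", rm=1.0)
        curve = response_curves(model, "x1", mode="only",
                                presence=pres, background=uniform_background)
        lo, hi = model.feature_spec.normalizers["x1"]
        peak = curve.loc[curve["suitability"].idxmax(), "x1"]
        assert abs(peak - 0.6) <= 0.05 * (hi - lo)
        assert curve["suitability"].between(0, 1).all()

    def test_marginal_equals_only_for_single_variable_model(self, uniform_background, rng):
        pres = gibbs_presences(rng, uniform_background, 2.0, m=200)
        model = fit_from_tables(pres[["x1"]], uniform_background[["x1"]], classes="L", rm=1.0)
        marg = response_curves(model, "x1", mode="marginal")
        only = response_curves(model, "x1", mode="only",
                               presence=pres[["x1"]], background=uniform_background[["x1"]])
        np.testing.assert_allclose(marg["suitability"], only["suitability"], atol=1e-9)


class TestReplicateScheme:
    @pytest.mark.parametrize(
        "n,level,expected",
        [
            (534, "genus", ("subsample", 0.25)),
            (259, "species", ("subsample", 0.30)),
            (32, "species", ("subsample", 0.40)),
            (22, "species", ("subsample", 0.40)),
            (8, "species", ("bootstrap", 0.0)),
            (17, "species", ("subsample", 0.40)),  # gap range, mapped with warning
        ],
    )
    def test_sample_size_rules(self, n, level, expected):
        method, frac, n_rep = replicate_scheme(n, level)
        assert (method, frac) == expected
        assert n_rep == 10
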
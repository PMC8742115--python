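"""Maximum-entropy fitter, features, prediction transforms and AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from nichemax.grid_io import EnvStack, GridSpec
from nichemax.maxent_core import (auc, build_features, feature_matrix,
                                  fit_maxent, predict, sample_background)


def auc_oracle(pres, bg):
    """Exhaustive pair enumeration: wins + half ties over all pairs."""
    wins = sum(1.0 if p > b else 0.5 if p == b else 0.0
               for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


def landscape_matrix(model, presence, background):
    land = pd.concat([presence, background], ignore_index=True)
    return feature_matrix(model.features, land)


class TestAuc:
    @pytest.mark.parametrize("pres,bg,expected", [
        ([0.9, 0.8], [0.2, 0.1], 1.0),
        ([0.8, 0.5], [0.5, 0.2], 0.875),
        ([0.1, 0.2], [0.8, 0.9], 0.0),
    ])
    def test_small_examples(self, pres, bg, expected):
        assert auc(pres, bg) == pytest.approx(expected, abs=1e-12)

    def test_identical_multisets_give_half(self):
        with pytest.warns(UserWarning):
            assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5
        assert auc([0.3, 0.7], [0.7, 0.3]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 50, 2)
        # discretized scores force plenty of ties
        pres = np.round(rng.uniform(0, 1, m), 1)
        bg = np.round(rng.uniform(0, 1, n), 1)
        assert auc(pres, bg) == pytest.approx(auc_oracle(pres, bg), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestBuildFeatures:
    def test_linear_only_is_minmax_scaling(self):
        df = pd.DataFrame({"v": [2.0, 4.0, 6.0]})
        specs, F = build_features(df, ("linear",))
        assert len(specs) == 1
        np.testing.assert_allclose(F[:, 0], [0.0, 0.5, 1.0])

    def test_hinge_endpoint_identities(self):
        df = pd.DataFrame({"v": np.linspace(0, 10, 101)})
        specs, F = build_features(df, ("hinge",), n_hinge_knots=3)
        fwd = [(i, s) for i, s in enumerate(specs) if s.orientation == "forward"]
        for i, s in fwd:
            at_knot = s.evaluate(pd.DataFrame({"v": [s.knot]}))
            at_max = s.evaluate(pd.DataFrame({"v": [10.0]}))
            assert at_knot[0] == pytest.approx(0.0, abs=1e-12)
            assert at_max[0] == pytest.approx(1.0, abs=1e-12)

    def test_column_count_formula(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 0.0]})
        specs, F = build_features(df, ("linear", "quadratic", "product"))
        assert F.shape[1] == 2 + 2 + 1  # p linear + p quadratic + C(p,2) products

    def test_clamping_outside_training_range(self):
        df = pd.DataFrame({"v": [0.0, 10.0]})
        specs, _ = build_features(df, ("linear",))
        out = specs[0].evaluate(pd.DataFrame({"v": [-5.0, 15.0]}))
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_zero_variance_skips_nonlinear_with_warning(self):
        df = pd.DataFrame({"v": [3.0, 3.0, 3.0], "w": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            specs, _ = build_features(df, ("linear", "quadratic", "hinge"))
        v_specs = [s for s in specs if s.source_vars == ("v",)]
        assert [s.feature_class for s in v_specs] == ["linear"]


class TestSampleBackground:
    def test_all_cells_when_n_equals_total(self, small_stack):
        cells = sample_background(small_stack, 100, seed=0)
        assert len(cells) == 100
        assert len(np.unique(cells[:, 0] * 10 + cells[:, 1])) == 100

    def test_deterministic_under_seed(self, small_stack):
        a = sample_background(small_stack, 30, seed=7)
        b = sample_background(small_stack, 30, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_uniformity_over_seeds(self, small_stack):
        # cell (0,0) inclusion frequency over many seeds ~ Binomial(n_seeds, 30/100)
        n_seeds, n, N = 1000, 30, 100
        hits = sum(
            bool(((sample_background(small_stack, n, seed=s)) == [0, 0]).all(axis=1).any())
            for s in range(n_seeds)
        )
        p = n / N
        sd = math.sqrt(n_seeds * p * (1 - p))
        assert abs(hits - n_seeds * p) < 2.58 * sd  # 99% normal bound

    def test_fully_masked_stack_rejected(self, small_grid):
        stack = EnvStack(small_grid, {"v": np.ones(small_grid.shape)}, "c",
                         np.ones(small_grid.shape, dtype=bool))
        with pytest.raises(ValueError):
            sample_background(stack, 5, seed=0)


class TestFitMaxent:
    def test_matched_means_give_zero_weights(self):
        # presence distribution identical to landscape -> uniform optimum
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        pres = pd.DataFrame({"v": vals})
        bg = pd.DataFrame({"v": np.tile(vals, 10)})
        m = fit_maxent(pres, bg, feature_classes=("linear",), beta_override=0.0)
        assert m.training["gain"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(m.lambdas, 0.0, atol=1e-6)

    def test_binary_feature_approaches_log2_gain(self):
        # all presences at f=1, half of the landscape at f=1: the
        # unregularized gain supremum is log 2, approached at convergence
        pres = pd.DataFrame({"v": [1.0]})
        bg = pd.DataFrame({"v": [1.0] * 10 + [0.0] * 11})  # landscape: 11 ones, 11 zeros
        m = fit_maxent(pres, bg, feature_classes=("linear",), beta_override=0.0,
                       tol=1e-7, max_iter=10_000)
        assert m.training["gain"] == pytest.approx(math.log(2), abs=1e-4)
        F = landscape_matrix(m, pres, bg)
        eta = F @ m.lambdas
        q = np.exp(eta - logsumexp(eta))
        assert q @ F[:, 0] == pytest.approx(1.0, abs=1e-3)

    def test_single_feature_matches_brute_force_1d_solver(self):
        rng = np.random.default_rng(0)
        pres = pd.DataFrame({"v": rng.uniform(0.5, 1.0, 40)})
        bg = pd.DataFrame({"v": rng.uniform(0.0, 1.0, 200)})
        beta = 0.05
        m = fit_maxent(pres, bg, feature_classes=("linear",), beta_override=beta,
                       tol=1e-10, max_iter=50_000)
        F = landscape_matrix(m, pres, bg)
        f = F[:, 0]
        pmean = f[:40].mean()

        def neg_gain(lam):
            eta = lam * f
            return -(pmean * lam - logsumexp(eta) + math.log(len(f)) - beta * abs(lam))

        res = minimize_scalar(neg_gain, bounds=(-100, 100), method="bounded",
                              options={"xatol": 1e-12})
        assert m.training["gain"] == pytest.approx(-res.fun, abs=1e-4)
        assert m.lambdas[0] == pytest.approx(res.x, abs=1e-3)

    def test_kkt_box_condition_at_convergence(self, recovery):
        m = recovery["model"]
        F = landscape_matrix(m, recovery["presence"], recovery["background"])
        npres = m.training["n_presence"]
        eta = F @ m.lambdas
        q = np.exp(eta - logsumexp(eta))
        resid = np.abs(q @ F - F[:npres].mean(axis=0))
        assert np.all(resid <= m.betas + 1e-3)

    def test_raw_scores_sum_to_one_over_landscape(self, recovery):
        m = recovery["model"]
        F = landscape_matrix(m, recovery["presence"], recovery["background"])
        raw = np.exp(F @ m.lambdas - m.logZ)
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gain_nonnegative_and_auc_reasonable(self, recovery):
        assert recovery["model"].training["gain"] > 0
        assert 0.5 < recovery["model"].training["train_auc"] <= 1.0

    def test_doubling_beta_never_increases_l1_norm(self):
        rng = np.random.default_rng(3)
        pres = pd.DataFrame({"a": rng.normal(1, 1, 60), "b": rng.normal(0, 1, 60)})
        bg = pd.DataFrame({"a": rng.normal(0, 1, 300), "b": rng.normal(0, 1, 300)})
        m1 = fit_maxent(pres, bg, feature_classes=("linear", "quadratic"),
                        reg_multiplier=1.0, tol=1e-8)
        m2 = fit_maxent(pres, bg, feature_classes=("linear", "quadratic"),
                        reg_multiplier=2.0, tol=1e-8)
        assert np.abs(m2.lambdas).sum() <= np.abs(m1.lambdas).sum() + 1e-8

    def test_no_presences_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(pd.DataFrame({"v": []}), pd.DataFrame({"v": [1.0]}))

    def test_nonfinite_features_rejected(self):
        pres = pd.DataFrame({"v": [1.0, np.nan]})
        bg = pd.DataFrame({"v": [0.0, 1.0]})
        with pytest.raises(ValueError, match="v"):
            fit_maxent(pres, bg, feature_classes=("linear",))

    def test_model_json_round_trip(self, recovery, tmp_path):
        m = recovery["model"]
        p = tmp_path / "model.json"
        m.to_json(p)
        from nichemax.maxent_core import MaxEntModel
        m2 = MaxEntModel.from_json(p)
        np.testing.assert_allclose(m2.lambdas, m.lambdas)
        df = recovery["presence"].head(20)
        np.testing.assert_allclose(m2.predict_cloglog(df), m.predict_cloglog(df))


class TestPredict:
    def test_uniform_model_cloglog_closed_form(self, small_stack):
        # a zero-weight model assigns q = 1/N and cloglog 1 - e^{-1}
        df = small_stack.table()
        pres, bg = df.head(5), df
        m = fit_maxent(pres, bg, feature_classes=("linear",), beta_override=1e9)
        np.testing.assert_allclose(m.lambdas, 0.0)
        smap = predict(m, small_stack, "cloglog")
        np.testing.assert_allclose(smap.values, 1.0 - math.exp(-1.0), rtol=1e-9)

    def test_cloglog_preserves_raw_ranking(self, recovery):
        m = recovery["model"]
        stack = recovery["stack"]
        raw = predict(m, stack, "raw").values.ravel()
        clog = predict(m, stack, "cloglog").values.ravel()
        ok = np.isfinite(raw)
        # monotone transform: sorting by raw must leave cloglog sorted
        # (floating-point saturation may introduce ties, hence non-strict)
        assert np.all(np.diff(clog[ok][np.argsort(raw[ok])]) >= 0)

    def test_training_cells_score_as_in_training(self, recovery):
        m = recovery["model"]
        pres = recovery["presence"]
        direct = m.predict_cloglog(pres)
        smap = predict(m, recovery["stack"], "cloglog")
        cells = recovery["occurrences"].cells()
        np.testing.assert_allclose(smap.values[cells[:, 0], cells[:, 1]], direct, rtol=1e-12)

    def test_missing_layer_named_in_error(self, recovery, small_grid):
        stack = EnvStack(small_grid, {"BIO1": np.ones(small_grid.shape)}, "x")
        with pytest.raises(KeyError, match="BIO9"):
            predict(recovery["model"], stack)

    def test_cloglog_in_unit_interval_with_nodata(self, recovery):
        stack = recovery["stack"]
        mask = np.zeros(stack.grid.shape, dtype=bool)
        mask[0, :] = True
        masked = EnvStack(stack.grid, dict(stack.layers), stack.scenario, mask)
        smap = predict(recovery["model"], masked, "cloglog")
        assert np.all(np.isnan(smap.values[0, :]))
        vals = smap.values[~mask]
        assert np.all((vals >= 0) & (vals <= 1))
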
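"""Train/test splitting, blend regressors, shadow selection, evaluation."""

import numpy as np
import pandas as pd
import pytest

from nutriwin.blends import (
    BlendConfig,
    BlendRegressor,
    ShadowFeatureSelector,
    evaluate_predictions,
    run_blend_analysis,
    spearman_fisher_ci,
    split_train_test,
)
from nutriwin.detect import AgeWindow

from conftest import make_cohort


class TestSplit:
    def test_sizes_293(self, small_dictionary):
        t = make_cohort(n=293, dictionary=small_dictionary)
        train, test = split_train_test(t, 0.25, seed=0)
        assert (train.n, test.n) == (220, 73)

    def test_even_split_small(self, small_dictionary):
        t = make_cohort(n=8, dictionary=small_dictionary)
        train, test = split_train_test(t, 0.5, seed=0)
        assert (train.n, test.n) == (4, 4)

    def test_disjoint_union(self, small_dictionary):
        t = make_cohort(n=40, dictionary=small_dictionary)
        train, test = split_train_test(t, 0.25, seed=5)
        ids = set(train.data.subject_id) | set(test.data.subject_id)
        assert len(ids) == 40
        assert not (set(train.data.subject_id) & set(test.data.subject_id))

    def test_seed_reproducibility(self, small_dictionary):
        t = make_cohort(n=40, dictionary=small_dictionary)
        a1, b1 = split_train_test(t, 0.25, seed=7)
        a2, b2 = split_train_test(t, 0.25, seed=7)
        pd.testing.assert_frame_equal(a1.data, a2.data)
        pd.testing.assert_frame_equal(b1.data, b2.data)
        a3, _ = split_train_test(t, 0.25, seed=8)
        assert not a1.data.equals(a3.data)

    def test_degenerate_split_rejected(self, small_dictionary):
        t = make_cohort(n=9, dictionary=small_dictionary)
        with pytest.raises(ValueError, match="degenerate|at least"):
            split_train_test(t, 0.1, seed=0)


class TestEvaluate:
    def test_fisher_ci_closed_form(self):
        lo, hi = spearman_fisher_ci(0.67, 73)
        assert round(lo, 2) == 0.52
        assert round(hi, 2) == 0.78

    def test_perfect_monotone_rho_one(self):
        x = np.arange(10.0)
        ev = evaluate_predictions(x, x ** 3)
        assert ev.rho == pytest.approx(1.0)

    def test_identical_vectors_zero_rmse(self):
        x = np.random.default_rng(0).normal(size=20)
        ev = evaluate_predictions(x, x)
        assert ev.rmse == 0.0

    def test_ci_contains_rho(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        ev = evaluate_predictions(a, a + b)
        assert ev.ci_low <= ev.rho <= ev.ci_high

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate_predictions(np.ones(10), np.arange(10.0))


def _signal_data(n=150, p=8, n_true=2, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{j}" for j in range(p)])
    y = sum(X[f"f{j}"] for j in range(n_true)) + rng.normal(0, noise, n)
    return X, y.to_numpy()


class TestBlendRegressor:
    def test_perfect_predictor_ranked_first(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"good": rng.normal(size=100)})
        y = 3 * X["good"].to_numpy() + rng.normal(0, 0.01, 100)
        for model in ("elastic_net", "random_forest"):
            reg = BlendRegressor(model=model, n_trees=50, cv_folds=5,
                                 seed=0).fit(X, y)
            assert reg.importances_.index[0] == "good"
            ev = evaluate_predictions(reg.predict(X), y)
            assert ev.rho > 0.99

    def test_elastic_net_recovers_true_support(self):
        X, y = _signal_data(noise=0.05)
        reg = BlendRegressor(model="elastic_net", cv_folds=5, seed=0)
        reg.fit(X, y)
        top2 = set(reg.importances_.index[:2])
        assert top2 == {"f0", "f1"}

    def test_elastic_net_null_shrinks_to_empty(self):
        """Permuted outcome: the one-SE penalty wipes out (nearly) all
        coefficients in most seeds."""
        wins = 0
        for seed in range(5):
            X, y = _signal_data(seed=seed)
            y = np.random.default_rng(100 + seed).permutation(y)
            reg = BlendRegressor(model="elastic_net", cv_folds=5,
                                 seed=seed).fit(X, y)
            if (np.abs(reg.model_.coef_) < 1e-6).all():
                wins += 1
        assert wins >= 3

    def test_forest_importance_finds_signal(self):
        X, y = _signal_data(n=200, noise=0.2)
        reg = BlendRegressor(model="random_forest", n_trees=100, cv_folds=5,
                             seed=0).fit(X, y)
        assert set(reg.importances_.index[:2]) == {"f0", "f1"}

    def test_predict_original_scale(self):
        X, y = _signal_data(noise=0.05)
        y = y * 10 + 100
        reg = BlendRegressor(model="elastic_net", cv_folds=5, seed=0)
        reg.fit(X, y)
        pred = reg.predict(X)
        assert abs(pred.mean() - y.mean()) < 2.0

    def test_constant_outcome_rejected(self):
        X, _ = _signal_data()
        with pytest.raises(ValueError, match="constant"):
            BlendRegressor(model="elastic_net").fit(X, np.ones(len(X)))

    def test_sklearn_get_set_params(self):
        reg = BlendRegressor()
        params = reg.get_params()
        assert params["model"] == "random_forest"
        reg.set_params(model="elastic_net", cv_folds=3)
        assert reg.model == "elastic_net" and reg.cv_folds == 3


class TestShadowSelector:
    def test_strong_signals_confirmed_noise_rejected(self):
        X, y = _signal_data(n=200, p=10, n_true=3, noise=0.3, seed=4)
        sel = ShadowFeatureSelector(n_trees=60, n_rounds=20, seed=0)
        sel.fit(X, y)
        chosen = set(sel.selected_names_)
        assert {"f0", "f1", "f2"} <= chosen
        assert len(chosen - {"f0", "f1", "f2"}) <= 1

    def test_pure_noise_mostly_empty(self):
        import warnings

        empties = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(120, 8)),
                             columns=[f"f{j}" for j in range(8)])
            y = rng.normal(size=120)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                sel = ShadowFeatureSelector(n_trees=40, n_rounds=12,
                                            seed=seed).fit(X, y)
            empties += len(sel.selected_names_) == 0
        assert empties >= 3

    def test_empty_confirmation_warns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(120, 8)),
                         columns=[f"f{j}" for j in range(8)])
        y = rng.normal(size=120)
        with pytest.warns(UserWarning, match="no features"):
            ShadowFeatureSelector(n_trees=40, n_rounds=12, seed=0).fit(X, y)

    def test_dominant_signal_always_hits(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(150, 6)),
                         columns=[f"f{j}" for j in range(6)])
        y = 10 * X["f0"].to_numpy() + rng.normal(0, 1, 150)
        sel = ShadowFeatureSelector(n_trees=40, n_rounds=10, seed=0)
        sel.fit(X, y)
        assert "f0" in sel.selected_names_

    def test_transform_keeps_confirmed_columns(self):
        X, y = _signal_data(n=200, p=6, n_true=2, noise=0.2, seed=5)
        sel = ShadowFeatureSelector(n_trees=60, n_rounds=16, seed=1)
        Xt = sel.fit(X, y).transform(X)
        assert Xt.shape[1] == sel.support_.sum()


class TestRunAnalysis:
    def config(self, **kw):
        base = dict(model="elastic_net", cv_folds=5, n_trees=40,
                    use_shadow_selection=False, seed=0)
        base.update(kw)
        return BlendConfig(**base)

    def test_across_ages_smoke(self, small_dictionary):
        t = make_cohort(n=80, dictionary=small_dictionary,
                        nutrients=("Iron", "Zinc", "DHA"),
                        effect=0.03, effect_nutrient="Iron")
        results = run_blend_analysis(t, None, self.config())
        (r,) = results
        assert np.isfinite(r.rho) and r.ci_low <= r.rho <= r.ci_high
        assert r.rmse >= 0
        assert (r.n_train, r.n_test) == (60, 20)

    def test_empty_window_candidates_noted(self, small_dictionary):
        t = make_cohort(n=80, dictionary=small_dictionary)
        w = AgeWindow(6, 30)          # no selected nutrients attached
        w2 = AgeWindow(31, 60)
        results = run_blend_analysis(
            t, [w, w2], self.config(scope="per_window",
                                    nutrient_set="window_preselected"))
        assert all(r.note == "no combination identified" for r in results)

    def test_targeted_categories_give_one_row_each(self, small_dictionary):
        t = make_cohort(n=80, dictionary=small_dictionary,
                        nutrients=("Iron", "Zinc", "DHA"))
        rows = []
        for cat in ("micronutrients", "fatty_acids"):
            rows += run_blend_analysis(t, None,
                                       self.config(nutrient_set=cat))
        assert len(rows) == 2
        assert rows[0].nutrient_set == "micronutrients"

    def test_per_window_with_preselected(self, small_dictionary):
        t = make_cohort(n=120, seed=6, dictionary=small_dictionary,
                        nutrients=("Iron", "Zinc", "DHA"),
                        effect=0.05, effect_nutrient="Zinc")
        w = AgeWindow(6, 60)
        w.selected_nutrients = [("Zinc", 1, 0.8), ("Iron", 1, 0.6)]
        (r,) = run_blend_analysis(
            t, [w], self.config(scope="per_window",
                                nutrient_set="window_preselected"))
        assert r.note == ""
        assert set(r.selected) <= {"Zinc", "Iron"}

    def test_model_both_emits_two_rows(self, small_dictionary):
        t = make_cohort(n=80, dictionary=small_dictionary,
                        effect=0.04, effect_nutrient="Iron")
        results = run_blend_analysis(t, None, self.config(model="both"))
        assert [r.model for r in results] == ["elastic_net", "random_forest"]
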
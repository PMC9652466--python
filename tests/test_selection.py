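"""SVM model selection: kernel, nested CV, exhaustive search, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC, SVR

import tpdcnet as t
from tpdcnet.selection import (
    ModelResult,
    _PrecomputedSVM,
    adaptive_epsilon,
    median_sigma,
)

vec = st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6)


class TestRBFKernel:
    def test_identical_points_give_one(self):
        assert t.rbf_kernel([1.0, 2.0], [1.0, 2.0], sigma=0.7) == 1.0

    def test_closed_form_at_two_sigma_squared(self):
        sigma = 1.3
        x = np.zeros(2)
        x2 = np.array([sigma * np.sqrt(2), 0.0])
        assert t.rbf_kernel(x, x2, sigma) == pytest.approx(np.exp(-1), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(vec, st.floats(0.1, 5))
    def test_symmetry_and_range(self, v, sigma):
        x = np.array(v)
        y = x[::-1].copy()
        k1 = t.rbf_kernel(x, y, sigma)
        assert k1 == pytest.approx(t.rbf_kernel(y, x, sigma))
        assert 0 <= k1 <= 1  # exp may underflow to exactly 0 at tiny sigma

    def test_rejects_bad_inputs(self):
        with pytest.raises(t.TpdcError):
            t.rbf_kernel([1.0], [1.0, 2.0], 1.0)
        with pytest.raises(t.TpdcError):
            t.rbf_kernel([np.inf], [0.0], 1.0)
        with pytest.raises(t.TpdcError):
            t.rbf_kernel([0.0], [1.0], 0.0)


class TestFastSVMEquivalence:
    """The libsvm fast path must reproduce the public estimators exactly."""

    def test_regression_matches_public_svr(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        sig = median_sigma(X)
        K = np.exp(-np.sum((X[:, None] - X[None]) ** 2, -1) / (2 * sig**2))
        eps = adaptive_epsilon(y)
        fast = _PrecomputedSVM("regression", epsilon=eps).fit(K, y)
        pub = SVR(kernel="precomputed", C=1.0, epsilon=eps).fit(K, y)
        assert np.allclose(fast.predict(K), pub.predict(K), atol=1e-8)

    def test_classification_matches_public_svc(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            X = rng.normal(size=(50, 3))
            y = np.where(X[:, 0] + 0.5 * rng.normal(size=50) > 0, "PD", "HC")
            if len(np.unique(y)) < 2:
                continue
            sig = median_sigma(X)
            K = np.exp(-np.sum((X[:, None] - X[None]) ** 2, -1) / (2 * sig**2))
            fast = _PrecomputedSVM("classification").fit(K, y)
            pub = SVC(kernel="precomputed", C=1.0).fit(K, y)
            assert (fast.predict(K) == pub.predict(K)).all()


class TestNestedCV:
    def test_noiseless_linear_response_recovered(self):
        spec = t.CohortSpec(n_per_group=25, true_subset=("CB->SC", "MC->SC"),
                            response_coeffs=(0.8, 0.6), noise_sd=0.0, seed=0)
        co = t.simulate_cohort(spec)
        res = t.nested_cv_evaluate(co, ("CB->SC", "MC->SC"), run_inner=False)
        assert res.mean_score >= 0.99

    def test_pure_noise_response_scores_near_zero(self):
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            co = t.simulate_cohort(t.CohortSpec(n_per_group=25, seed=seed))
            co["response"] = rng.normal(size=len(co))
            res = t.nested_cv_evaluate(co, ("CB->SC", "MC->SC", "PFC->MC"),
                                       cv=t.CVConfig(seed=seed), run_inner=False)
            scores.append(res.mean_score)
        assert np.mean(scores) <= 0.1

    def test_outer_fold_sizes_partition_n19(self):
        co = t.simulate_cohort(t.CohortSpec(n_per_group=19, seed=1))
        sub = co.query("group == 'PD' and session == 'baseline'")
        sub = sub.assign(response=np.arange(len(sub), dtype=float))
        res = t.nested_cv_evaluate(sub, ("CB->SC",), run_inner=False)
        assert len(res.fold_scores) == 5
        from sklearn.model_selection import KFold

        sizes = sorted(len(te) for _, te in
                       KFold(5, shuffle=True, random_state=0).split(np.zeros(19)))
        assert sizes == [3, 4, 4, 4, 4]

    def test_inner_loop_present_but_does_not_change_outer_scores(self, planted_cohort):
        subset = ("CB->SC", "MC->SC")
        with_inner = t.nested_cv_evaluate(planted_cohort, subset, run_inner=True)
        without = t.nested_cv_evaluate(planted_cohort, subset, run_inner=False)
        assert np.allclose(with_inner.fold_scores, without.fold_scores)
        assert with_inner.inner_scores is not None
        assert len(with_inner.inner_scores) == 5

    def test_missing_feature_rejected(self, planted_cohort):
        with pytest.raises(t.TpdcError, match="not in table"):
            t.nested_cv_evaluate(planted_cohort, ("nope",))


class TestExhaustiveSearch:
    def test_three_features_give_seven_subsets(self, planted_cohort):
        ranked = t.exhaustive_search(
            planted_cohort, feature_cols=["CB->SC", "MC->SC", "PFC->MC"])
        assert len(ranked) == 7

    def test_enumeration_space_is_two_to_the_twenty(self):
        assert t.search_space_size(20) == 2**20 == 1_048_576

    def test_budget_guard_refuses_with_count(self, planted_cohort):
        with pytest.raises(t.TpdcError, match="1048555|budget"):
            t.exhaustive_search(planted_cohort, budget=100)

    def test_deterministic_ranking(self, planted_cohort):
        kw = dict(feature_cols=["CB->SC", "MC->SC", "PFC->MC", "BS->MC"],
                  cv=t.CVConfig(seed=3))
        a = t.exhaustive_search(planted_cohort, **kw)
        b = t.exhaustive_search(planted_cohort, **kw)
        assert [r.subset for r in a] == [r.subset for r in b]
        assert all(np.array_equal(x.fold_scores, y.fold_scores)
                   for x, y in zip(a, b))

    def test_engine_agrees_with_reference_evaluator(self, planted_cohort):
        svm, cv = t.SVMConfig(), t.CVConfig(seed=2)
        ranked = t.exhaustive_search(planted_cohort, svm, cv,
                                     feature_cols=["CB->SC", "MC->SC"])
        for r in ranked:
            ref = t.nested_cv_evaluate(planted_cohort, r.subset, svm, cv,
                                       run_inner=False)
            assert np.allclose(r.fold_scores, ref.fold_scores)

    def test_classification_search_separates_groups(self, separable_cohort):
        base = separable_cohort.query("session == 'baseline'")
        ranked = t.exhaustive_search(
            base, t.SVMConfig(task="classification"), t.CVConfig(seed=0),
            max_features=2,
            feature_cols=["CB->SC", "MC->SC", "PFC->MC", "BS->CB"])
        best = t.select_optimal(ranked)
        assert best.mean_score > 0.7
        assert set(best.subset) & {"CB->SC", "MC->SC"}


class TestSelectOptimal:
    def _mr(self, name, scores):
        scores = np.asarray(scores, dtype=float)
        se = float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
        return ModelResult(subset=(name,), fold_scores=scores,
                           mean_score=float(scores.mean()), score_se=se)

    def test_highest_mean_wins(self):
        results = [self._mr("a", [0.70] * 5), self._mr("b", [0.71] * 5),
                   self._mr("c", [0.65] * 5)]
        assert t.select_optimal(results).subset == ("b",)

    def test_tie_broken_by_standard_error(self):
        noisy = ModelResult(("a",), np.array([0.60, 0.80, 0.70, 0.75, 0.65]),
                            0.70, 0.10)
        tight = ModelResult(("b",), np.array([0.67, 0.73, 0.70, 0.71, 0.69]),
                            0.70, 0.03)
        assert t.select_optimal([noisy, tight]).subset == ("b",)

    def test_tie_broken_by_subset_size_then_name(self):
        small = ModelResult(("b",), np.full(5, 0.7), 0.7, 0.01)
        large = ModelResult(("a", "c"), np.full(5, 0.7), 0.7, 0.01)
        assert t.select_optimal([large, small]).subset == ("b",)
        first = ModelResult(("a",), np.full(5, 0.7), 0.7, 0.01)
        assert t.select_optimal([small, first]).subset == ("a",)

    def test_empty_list_rejected(self):
        with pytest.raises(t.TpdcError):
            t.select_optimal([])


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array(["PD", "PD", "HC", "HC"])
        m = t.classification_metrics(y, y)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (100, 100, 100)

    def test_confusion_count_arithmetic(self):
        y_true = np.array(["PD"] * 19 + ["HC"] * 19)
        y_pred = np.array(["PD"] * 18 + ["HC"] + ["PD"] * 2 + ["HC"] * 17)
        m = t.classification_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(100 * 35 / 38)
        assert m["sensitivity"] == pytest.approx(100 * 18 / 19)
        assert m["specificity"] == pytest.approx(100 * 17 / 19)

    def test_all_positive_predictions(self):
        y_true = np.array(["PD", "HC", "PD", "HC"])
        y_pred = np.array(["PD"] * 4)
        m = t.classification_metrics(y_true, y_pred)
        assert m["sensitivity"] == 100 and m["specificity"] == 0

    def test_absent_class_flagged_nan(self):
        m = t.classification_metrics(np.array(["HC", "HC"]),
                                     np.array(["HC", "HC"]))
        assert np.isnan(m["sensitivity"])


class TestShapleyAggregation:
    def test_zero_phis_aggregate_to_zero(self):
        df = pd.DataFrame({"f1": [0.0, 0.0], "f2": [0.0, 0.0],
                           "group": ["PD", "HC"]})
        agg = t.aggregate_shapley([df, df])
        assert (agg.to_numpy() == 0).all()

    def test_single_fold_equals_mean_abs(self):
        df = pd.DataFrame({"f1": [1.0, -3.0], "f2": [0.5, 0.5],
                           "group": ["PD", "PD"]})
        agg = t.aggregate_shapley([df])
        assert agg.loc["f1", "PD"] == pytest.approx(2.0)
        assert agg.loc["f2", "PD"] == pytest.approx(0.5)

    def test_sign_flip_invariance(self):
        df = pd.DataFrame({"f1": [1.0, -2.0], "group": ["PD", "PD"]})
        flipped = df.copy()
        flipped.loc[0, "f1"] = -1.0
        a = t.aggregate_shapley([df])
        b = t.aggregate_shapley([flipped])
        assert a.equals(b)

    def test_inconsistent_features_rejected(self):
        a = pd.DataFrame({"f1": [0.1], "group": ["PD"]})
        b = pd.DataFrame({"f2": [0.1], "group": ["PD"]})
        with pytest.raises(t.TpdcError, match="inconsistent"):
            t.aggregate_shapley([a, b])

    def test_shapley_by_fold_local_structure(self, planted_cohort):
        agg = t.shapley_by_fold(planted_cohort, ("CB->SC", "MC->SC"),
                                cv=t.CVConfig(seed=0))
        assert set(agg.index) == {"CB->SC", "MC->SC"}
        assert set(agg.columns) == {"PD", "HC"}
        assert (agg.to_numpy() >= 0).all()


class TestSelectorEstimator:
    def test_fit_predict_and_params(self, planted_cohort):
        feats = ["CB->SC", "MC->SC", "PFC->MC", "BS->MC"]
        X = planted_cohort[feats].to_numpy()
        y = planted_cohort["response"].to_numpy()
        sel = t.ExhaustiveSVMSelector(task="regression", max_features=2, seed=0)
        sel.fit(X, y, feature_names=feats)
        assert sel.n_enumerated_ == 2**4
        assert len(sel.results_) == 4 + 6
        pred = sel.predict(X)
        ss = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss > 0.5
        params = sel.get_params()
        assert params["max_features"] == 2
        sel2 = t.ExhaustiveSVMSelector(**params)
        assert sel2.get_params() == params
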
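"""Shapley attribution: axioms, oracle equivalence, global summaries."""

import numpy as np
import pytest

from conftest import make_feature_cohort
from voicepd.attribution import (
    NotTreeModelError,
    Tree,
    TreeEnsemble,
    coalition_value,
    extract_ensemble,
    global_importance,
    incremental_feature_curve,
    shap_explain,
    shapley_exact,
    tree_conditional_expectation,
)
from voicepd.modeling import ModelSpec, train_classifier


def toy_tree() -> Tree:
    """Depth-2 tree with hand-chosen covers.

            node0: x0 <= 0 ? (cover 100)
           /                \
     node1: x1 <= 1 ?     node2: leaf 5.0 (cover 40)
     (cover 60)
      /         \
    leaf 1.0   leaf 3.0
    (cover 45) (cover 15)
    """
    return Tree(
        feature=np.array([0, 1, -1, -1, -1]),
        threshold=np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
        left=np.array([1, 3, -1, -1, -1]),
        right=np.array([2, 4, -1, -1, -1]),
        value=np.array([0.0, 0.0, 5.0, 1.0, 3.0]),
        cover=np.array([100.0, 60.0, 40.0, 45.0, 15.0]),
        cmp="le",
    )


def random_ensemble(seed: int, d: int = 8, n: int = 80):
    """Small fitted XGBoost ensemble on random data, plus the data."""
    import xgboost

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = (X[:, 0] + 0.6 * X[:, 2] - 0.4 * X[:, 5] + 0.5 * rng.standard_normal(n) > 0).astype(int)
    model = xgboost.XGBClassifier(n_estimators=6, max_depth=3, n_jobs=1, random_state=seed)
    model.fit(X, y)
    return extract_ensemble(model), X


class TestTreeConditionalExpectation:
    def test_condition_on_all_features_follows_path(self):
        t = toy_tree()
        x = np.array([-1.0, 2.0])  # left at node0, right at node1 -> leaf 3.0
        assert tree_conditional_expectation(t, x, {0, 1}) == 3.0

    def test_condition_on_none_is_cover_weighted_mean(self):
        t = toy_tree()
        x = np.array([-1.0, 2.0])
        expected = (45 * 1.0 + 15 * 3.0 + 40 * 5.0) / 100
        assert tree_conditional_expectation(t, x, set()) == pytest.approx(expected)

    def test_partial_conditioning_hand_expansion(self):
        t = toy_tree()
        x = np.array([-1.0, 0.5])
        # conditioning on x0 only: follow left at node0, average node1
        expected = (45 * 1.0 + 15 * 3.0) / 60
        assert tree_conditional_expectation(t, x, {0}) == pytest.approx(expected)
        # conditioning on x1 only: average node0 children, follow x1 at node1
        expected = (60 * 1.0 + 40 * 5.0) / 100
        assert tree_conditional_expectation(t, x, {1}) == pytest.approx(expected)

    def test_unknown_feature_index_raises(self):
        t = toy_tree()
        with pytest.raises(IndexError):
            tree_conditional_expectation(t, np.array([1.0]), {1})


class TestShapleyAxioms:
    def test_dummy_feature_gets_zero(self):
        ens, X = random_ensemble(0)
        # append a feature no tree splits on
        x = np.concatenate([X[0], [99.0]])
        expl = shapley_exact(ens, x)
        assert expl.attributions[-1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_features_equal_attribution(self):
        # single tree splitting symmetrically on x0 and x1 with equal covers
        t = Tree(
            feature=np.array([0, 1, 1, -1, -1, -1, -1]),
            threshold=np.zeros(7),
            left=np.array([1, 3, 5, -1, -1, -1, -1]),
            right=np.array([2, 4, 6, -1, -1, -1, -1]),
            value=np.array([0, 0, 0, 0.0, 1.0, 1.0, 2.0]),
            cover=np.array([100.0, 50, 50, 25, 25, 25, 25]),
        )
        ens = TreeEnsemble([t], n_features=2)
        expl = shapley_exact(ens, np.array([1.0, 1.0]))
        assert expl.attributions[0] == pytest.approx(expl.attributions[1], abs=1e-12)

    def test_efficiency_sum_equals_prediction_minus_base(self):
        ens, X = random_ensemble(1)
        for i in range(3):
            expl = shapley_exact(ens, X[i])
            assert expl.base_value + expl.attributions.sum() == pytest.approx(
                ens.predict_raw(X[i]), abs=1e-6
            )


class TestTreeAlgorithmOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_enumeration(self, seed):
        ens, X = random_ensemble(seed)
        x = X[seed % X.shape[0]]
        exact = shapley_exact(ens, x)
        fast = shap_explain(ens, x[None, :])[0]
        np.testing.assert_allclose(fast.attributions, exact.attributions, atol=1e-6)
        assert fast.base_value == pytest.approx(exact.base_value, abs=1e-6)

    def test_additivity_every_instance(self):
        ens, X = random_ensemble(3)
        for expl, x in zip(shap_explain(ens, X[:10]), X[:10]):
            assert expl.base_value + expl.attributions.sum() == pytest.approx(
                ens.predict_raw(x), abs=1e-6
            )

    def test_single_split_tree_gives_all_to_split_feature(self):
        t = Tree(
            feature=np.array([1, -1, -1]),
            threshold=np.array([0.0, 0, 0]),
            left=np.array([1, -1, -1]),
            right=np.array([2, -1, -1]),
            value=np.array([0.0, -1.0, 2.0]),
            cover=np.array([10.0, 4.0, 6.0]),
        )
        ens = TreeEnsemble([t], n_features=3)
        x = np.array([0.0, 5.0, 0.0])
        expl = shap_explain(ens, x[None, :])[0]
        base = (4 * -1.0 + 6 * 2.0) / 10
        assert expl.attributions[1] == pytest.approx(2.0 - base, abs=1e-12)
        assert expl.attributions[0] == expl.attributions[2] == 0.0

    def test_lightgbm_and_forest_backends(self):
        import lightgbm
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 6))
        y = (X[:, 1] - X[:, 4] > 0).astype(int)
        for model in (
            lightgbm.LGBMClassifier(n_estimators=5, max_depth=3, verbose=-1,
                                    min_child_samples=5, n_jobs=1, random_state=0).fit(X, y),
            RandomForestClassifier(n_estimators=5, max_depth=3, random_state=0).fit(X, y),
        ):
            ens = extract_ensemble(model)
            x = X[0]
            exact = shapley_exact(ens, x)
            fast = shap_explain(ens, x[None, :])[0]
            np.testing.assert_allclose(fast.attributions, exact.attributions, atol=1e-6)

    def test_svm_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        y = (rng.random(30) < 0.5).astype(int)
        clf = train_classifier(ModelSpec(algorithm="svm"), X, y)
        with pytest.raises(NotTreeModelError):
            shap_explain(clf, X)

    def test_exact_dimension_guard(self):
        ens, _ = random_ensemble(0)
        with pytest.raises(ValueError, match="shap_explain"):
            shapley_exact(ens, np.zeros(16))


class TestGlobalImportance:
    def test_never_split_feature_ranked_last_with_zero_impact(self):
        ens, X = random_ensemble(2)
        Xp = np.column_stack([X, np.full(X.shape[0], 7.0)])
        expl = shap_explain(ens, Xp[:20])
        gi = global_importance(expl)
        assert gi.impacts[-1] == 0.0
        assert gi.ranking[-1] == Xp.shape[1] - 1

    def test_duplicate_explanations_same_ranking(self):
        ens, X = random_ensemble(4)
        expl = shap_explain(ens, X[:10])
        r1 = global_importance(expl).ranking
        r2 = global_importance(expl + expl).ranking
        assert r1 == r2

    def test_planted_signal_ranks_first(self):
        hits = 0
        for seed in range(10):
            cohort = make_feature_cohort(n=80, d=6, effect=2.5, seed=seed)
            clf = train_classifier(
                ModelSpec(algorithm="extreme_gradient_boosting", seed=seed),
                cohort.X.to_numpy(), cohort.y,
            )
            expl = shap_explain(clf, cohort.X.to_numpy())
            gi = global_importance(expl, feature_names=cohort.kept_features)
            hits += gi.ranking[0] == 0
        assert hits >= 9

    def test_empty_explanations_rejected(self):
        with pytest.raises(ValueError):
            global_importance([])


class TestIncrementalFeatureCurve:
    def test_planted_single_signal_saturates_at_one(self):
        cohort = make_feature_cohort(n=50, d=5, effect=3.0, seed=0)
        curve, saturation = incremental_feature_curve(
            cohort, cohort.kept_features, ModelSpec(algorithm="svm"), k_max=5
        )
        assert saturation == 1

    def test_null_cohort_curve_stays_flat(self):
        cohort = make_feature_cohort(n=200, d=5, effect=0.0, seed=1)
        curve, _ = incremental_feature_curve(
            cohort, cohort.kept_features, ModelSpec(algorithm="svm"), k_max=5
        )
        assert all(0.35 <= auc <= 0.65 for _, auc, _ in curve)

    def test_full_curve_point_matches_plain_loocv(self):
        from voicepd.modeling import loocv_evaluate

        cohort = make_feature_cohort(n=40, d=4, effect=1.5, seed=2)
        spec = ModelSpec(algorithm="svm")
        curve, _ = incremental_feature_curve(cohort, cohort.kept_features, spec, k_max=4)
        full = loocv_evaluate(spec, cohort)
        assert curve[-1][1] == pytest.approx(full.auc, abs=1e-12)
        assert curve[-1][2] == pytest.approx(full.accuracy, abs=1e-12)

    def test_k_max_clipped_with_warning(self, caplog):
        cohort = make_feature_cohort(n=30, d=3, effect=2.0, seed=3)
        with caplog.at_level("WARNING"):
            curve, _ = incremental_feature_curve(
                cohort, cohort.kept_features, ModelSpec(algorithm="svm"), k_max=10
            )
        assert len(curve) == 3
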
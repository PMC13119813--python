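"""Nested-CV classification: fold hygiene, selection, metrics, leakage guards."""

import numpy as np
import pandas as pd
import pytest

from gaitcog.classify import (
    CvConfig,
    ModelSpec,
    bootstrap_ci,
    evaluate,
    fit_predict,
    make_folds,
    nested_cv,
    rfe_select,
    rfecv_select,
    single_feature_roc,
)
from gaitcog.simulate import make_planted_binary_cohort


@pytest.fixture(scope="module")
def planted():
    return make_planted_binary_cohort(
        n_per_class=(60, 42), n_informative=5, n_noise=25, effect=0.9, seed=0
    )


class TestMakeFolds:
    def test_partition_and_stratification(self):
        labels = pd.Series(["normal"] * 60 + ["low"] * 42)
        ids = [f"P{i:03d}" for i in range(102)]
        folds = make_folds(labels, ids, n_folds=10, seed=42)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(102))
        for tr, te in folds:
            assert len(te) in (10, 11)
            assert set(tr).isdisjoint(te)
            pos = (labels.iloc[te] == "low").sum()
            assert pos in (4, 5)  # within one participant of 42/102 per fold

    def test_same_seed_same_folds(self):
        labels = pd.Series(["normal"] * 30 + ["low"] * 20)
        ids = [str(i) for i in range(50)]
        f1 = make_folds(labels, ids, 5, seed=3)
        f2 = make_folds(labels, ids, 5, seed=3)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            np.testing.assert_array_equal(te1, te2)


class TestSelection:
    def test_small_pool_fully_retained(self, planted):
        X, y = planted
        subset = rfe_select(X.iloc[:, :19], y, max_features=20)
        assert subset == list(X.columns[:19])

    def test_cap_equal_to_pool_is_identity(self, planted):
        X, y = planted
        assert rfe_select(X, y, max_features=X.shape[1]) == list(X.columns)

    def test_strong_separator_survives_rfe(self):
        X, y = make_planted_binary_cohort(
            n_per_class=(50, 50), n_informative=1, n_noise=30, effect=3.0, seed=1
        )
        subset = rfe_select(X, y, max_features=10)
        assert "signal_0" in subset

    def test_rfecv_deterministic_and_bounded(self, planted):
        X, y = planted
        ids = list(X.index)
        s1 = rfecv_select(X.iloc[:, :20], y, groups=ids, min_features=5, seed=11)
        s2 = rfecv_select(X.iloc[:, :20], y, groups=ids, min_features=5, seed=11)
        assert s1 == s2
        assert len(s1) >= 5

    def test_all_noise_collapses_to_minimum(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(7):
            X = pd.DataFrame(
                rng.normal(size=(90, 18)), columns=[f"n{i}" for i in range(18)]
            )
            X.index = [f"P{i}" for i in range(90)]
            y = pd.Series(["normal"] * 50 + ["low"] * 40, index=X.index)
            subset = rfecv_select(
                X, y, groups=list(X.index), min_features=5, seed=rep
            )
            hits += len(subset) == 5
        assert hits >= 4  # parsimony tie-break wins in the majority

    def test_single_class_rejected(self, planted):
        X, _ = planted
        y = pd.Series(["low"] * len(X), index=X.index)
        with pytest.raises(ValueError):
            rfe_select(X, y, max_features=5)


class TestFitPredict:
    def test_separable_data_perfect_accuracy(self):
        X, y = make_planted_binary_cohort(
            n_per_class=(40, 40), n_informative=2, n_noise=2, effect=6.0, seed=2
        )
        proba = fit_predict(X, y, X, ModelSpec(family="logistic_l2"))
        assert ((proba >= 0.5).astype(int) == (y == "low").astype(int)).all()

    @pytest.mark.parametrize(
        "family", ["logistic_l2", "svm_linear", "svm_rbf", "gradient_boosted_trees"]
    )
    def test_probabilities_in_unit_interval(self, planted, family):
        X, y = planted
        proba = fit_predict(X.iloc[:80], y.iloc[:80], X.iloc[80:], ModelSpec(family=family))
        assert proba.shape == (len(X) - 80,)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_no_test_side_refit(self, planted):
        """Scaling comes from the training fold: shifting the test matrix
        must shift predictions (a test-side refit would undo it)."""
        X, y = planted
        spec = ModelSpec(family="logistic_l2")
        base = fit_predict(X.iloc[:80], y.iloc[:80], X.iloc[80:], spec)
        shifted = fit_predict(X.iloc[:80], y.iloc[:80], X.iloc[80:] + 5.0, spec)
        assert not np.allclose(base, shifted)


class TestEvaluate:
    def test_confusion_arithmetic(self):
        # TP=3 FN=1 TN=4 FP=2
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.2, 0.3, 0.4, 0.9, 0.8])
        m = evaluate(p, y)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3, abs=1e-9)
        assert m["ppv"] == pytest.approx(0.6)
        assert m["npv"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_degenerate_auc_orientations(self):
        y = np.array([0, 1, 0, 1, 1])
        assert evaluate(y.astype(float), y)["roc_auc"] == 1.0
        assert evaluate(1.0 - y, y)["roc_auc"] == 0.0

    def test_zero_denominator_reported_missing(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.1, 0.3])  # no positive predictions
        assert np.isnan(evaluate(p, y)["ppv"])


class TestBootstrap:
    def test_perfect_predictions_degenerate_interval(self):
        y = np.array([0, 1] * 20)
        ci = bootstrap_ci(y.astype(float), y, "accuracy", reps=200, seed=1)
        assert ci == (1.0, 1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        p = rng.random(60)
        assert bootstrap_ci(p, y, "accuracy", reps=300, seed=9) == bootstrap_ci(
            p, y, "accuracy", reps=300, seed=9
        )

    def test_interval_contains_point_estimate_for_proportions(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.integers(0, 2, 80)
            p = np.clip(y + rng.normal(0, 0.6, 80), 0, 1)
            point = evaluate(p, y)["accuracy"]
            lo, hi = bootstrap_ci(p, y, "accuracy", reps=300, seed=int(rng.integers(1e6)))
            assert lo - 1e-9 <= point <= hi + 1e-9


class TestNestedCv:
    @pytest.fixture(scope="class")
    def cv_result(self, planted):
        X, y = planted
        config = CvConfig(outer_folds=10, bootstrap_reps=200, seed=42)
        return nested_cv(X, y, config, [ModelSpec(family="logistic_l2")])

    def test_stability_on_frequency_grid(self, cv_result):
        stab = cv_result["logistic_l2"].stability
        grid = np.round(np.arange(0, 11) / 10.0, 10)
        assert set(np.round(stab.to_numpy(), 10)).issubset(set(grid))

    def test_every_participant_predicted_once(self, cv_result, planted):
        X, _ = planted
        probs = cv_result["logistic_l2"].pooled_predictions
        assert probs.notna().all()
        assert len(probs) == len(X)

    def test_planted_features_dominate_stability(self, cv_result):
        stab = cv_result["logistic_l2"].stability.sort_values(ascending=False)
        top5 = set(stab.index[:5])
        assert top5 == {f"signal_{i}" for i in range(5)}

    def test_metrics_in_unit_interval(self, cv_result):
        metrics = cv_result["logistic_l2"].metrics
        for key, value in metrics.items():
            if np.isfinite(value):
                assert 0.0 <= value <= 1.0, key

    def test_gait_only_never_selects_clinical_columns(self, default_cohort):
        cohort, _ = default_cohort
        from gaitcog.cohort import exclude_cognitive, knn_impute

        imputed = knn_impute(exclude_cognitive(cohort))
        cols = [
            "clinical__updrs_iii",
            "physical_lifestyle__mini_best",
            "mocap__TurnPS_IMA_SLM",
            "mocap__TurnFS_IMA_SLM",
            "wearable__FW_LANK_MaxJerk",
            "wearable__FW_MANK_MaxJerk",
            "wearable__BW_T10_RMSAcc",
            "mocap__FW_Speed",
        ]
        config = CvConfig(
            outer_folds=5, inner_folds=3, rfecv_min_features=2,
            bootstrap_reps=100, configuration="gait_only", seed=1,
        )
        results = nested_cv(
            imputed.data[cols], cohort.label, config, [ModelSpec(family="logistic_l2")]
        )
        for subset in results["logistic_l2"].selected_features:
            for col in subset:
                assert col.startswith(("mocap__", "wearable__"))

    def test_deterministic_given_seed(self, planted):
        X, y = planted
        config = CvConfig(outer_folds=5, inner_folds=3, bootstrap_reps=100, seed=5)
        specs = [ModelSpec(family="logistic_l2")]
        r1 = nested_cv(X, y, config, specs)["logistic_l2"]
        r2 = nested_cv(X, y, config, specs)["logistic_l2"]
        pd.testing.assert_series_equal(r1.pooled_predictions, r2.pooled_predictions)
        assert r1.metric_cis == r2.metric_cis


class TestSingleFeatureRoc:
    def test_feature_equal_to_label_gives_unit_auc(self):
        labels = pd.Series(["normal"] * 10 + ["low"] * 8)
        feature = pd.Series((labels == "low").astype(float), name="f")
        auc, curve = single_feature_roc(feature, labels)
        assert auc == 1.0
        assert {"fpr", "tpr"} <= set(curve.columns)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        labels = pd.Series(np.where(rng.random(80) < 0.4, "low", "normal"))
        x = pd.Series(rng.normal(size=80), name="f")
        a1, _ = single_feature_roc(x, labels)
        a2, _ = single_feature_roc(np.exp(x).rename("g"), labels)
        assert a1 == pytest.approx(a2)

    def test_anti_predictive_feature_reported_below_half(self):
        labels = pd.Series(["normal"] * 10 + ["low"] * 10)
        feature = pd.Series(
            np.r_[np.ones(10), np.zeros(10)], name="f"
        )  # high in the negative class
        auc, _ = single_feature_roc(feature, labels)
        assert auc == 0.0

    def test_constant_feature_rejected(self):
        labels = pd.Series(["normal", "low"] * 5)
        with pytest.raises(ValueError):
            single_feature_roc(pd.Series(np.ones(10), name="f"), labels)
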
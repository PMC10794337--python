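"""Splits, metric panel, forest training, attribution, experiments."""

import numpy as np
import pandas as pd
import pytest

from macromorph.modeling import (
    ModelConfig,
    compute_classification_metrics,
    evaluate_classifier,
    feature_attribution,
    run_experiment,
    split_train_test,
    train_classifier,
    train_eval_regressor,
)
from macromorph.supertiles import SuperTileParams


def separable_table(n=120, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    return pd.DataFrame(
        {
            "class_id": np.r_[np.zeros(half, int), np.ones(half, int)],
            "f1": np.r_[rng.normal(0, 1, half), rng.normal(20, 1, half)],
            "f2": rng.normal(0, 1, n),
        }
    )


class TestSplit:
    def test_stratified_seventy_thirty(self):
        table = separable_table(100)
        cfg = ModelConfig(seed=0)
        tr_x, te_x, tr_y, te_y = split_train_test(table, table.class_id, cfg)
        assert len(tr_x) == 70 and len(te_x) == 30
        assert (pd.Series(tr_y).value_counts() == 35).all()
        assert (pd.Series(te_y).value_counts() == 15).all()

    def test_same_seed_same_split(self):
        table = separable_table(80)
        cfg = ModelConfig(seed=3)
        a = split_train_test(table, table.class_id, cfg)
        b = split_train_test(table, table.class_id, cfg)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_full_cohort_split_sizes(self, full_cohort):
        cfg = ModelConfig(seed=0)
        tr_x, te_x, _, _ = split_train_test(full_cohort, full_cohort.class_id, cfg)
        # 9304 rows at 70/30: 6513/2791 up to stratified rounding
        assert abs(len(tr_x) - 6513) <= 1
        assert abs(len(te_x) - 2791) <= 1
        assert len(tr_x) + len(te_x) == 9304

    def test_singleton_class_rejected(self):
        table = separable_table(40)
        table.loc[0, "class_id"] = 7
        with pytest.raises(ValueError, match="at least 2 rows"):
            split_train_test(table, table.class_id, ModelConfig())


class TestMetricPanel:
    def test_perfect_predictions(self):
        y = [0, 1, 2, 0, 1, 2]
        rep = compute_classification_metrics(y, y)
        for m in ("accuracy", "recall", "precision", "f1", "kappa", "mcc"):
            assert getattr(rep, m) == pytest.approx(1.0)

    def test_worked_binary_example(self):
        # confusion matrix TP=2 FP=1 FN=1 TN=2, hand-computed panel
        y_true = [1, 1, 1, 0, 0, 0]
        y_pred = [1, 1, 0, 0, 0, 1]
        rep = compute_classification_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.6667, abs=1e-4)
        assert rep.precision == pytest.approx(0.6667, abs=1e-4)
        assert rep.recall == pytest.approx(0.6667, abs=1e-4)
        assert rep.f1 == pytest.approx(0.6667, abs=1e-4)
        assert rep.kappa == pytest.approx(0.3333, abs=1e-4)
        assert rep.mcc == pytest.approx(0.3333, abs=1e-4)

    def test_random_predictions_have_null_agreement(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 6000)
        y_pred = rng.integers(0, 4, 6000)
        rep = compute_classification_metrics(y_true, y_pred)
        # kappa/MCC -> 0 within Monte-Carlo CI (~1/sqrt(n))
        assert abs(rep.kappa) < 0.05
        assert abs(rep.mcc) < 0.05

    def test_f1_is_harmonic_mean_identity(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 400)
        y_pred = rng.integers(0, 3, 400)
        rep = compute_classification_metrics(y_true, y_pred)
        # per-class harmonic mean, macro-averaged (0/0 counts as 0)
        f1s = []
        for k in range(3):
            tp = np.sum((y_true == k) & (y_pred == k))
            p = tp / max(np.sum(y_pred == k), 1)
            r = tp / max(np.sum(y_true == k), 1)
            f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
        assert rep.f1 == pytest.approx(np.mean(f1s), abs=1e-12)

    def test_single_class_auc_undefined_not_fabricated(self):
        rep = compute_classification_metrics([1, 1, 1], [1, 1, 0], np.ones((3, 2)) / 2)
        assert np.isnan(rep.auc)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compute_classification_metrics([0, 1], [0])


class TestClassifier:
    def test_disjoint_support_gives_perfect_cv(self):
        table = separable_table(200)
        cfg = ModelConfig(predictors=["f1", "f2"], cv_folds=5, seed=0)
        model, cv = train_classifier(table, table.class_id, cfg)
        assert cv.accuracy.mean() == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(4)
        table = separable_table(400, seed=4)
        shuffled = rng.permutation(table.class_id.to_numpy())
        cfg = ModelConfig(predictors=["f1", "f2"], cv_folds=5, seed=0)
        _, cv = train_classifier(table, shuffled, cfg)
        assert abs(cv.accuracy.mean() - 0.5) < 0.12  # 2 classes

    def test_deterministic_fold_metrics(self):
        table = separable_table(150, seed=5)
        cfg = ModelConfig(predictors=["f1", "f2"], cv_folds=5, seed=9)
        _, cv1 = train_classifier(table, table.class_id, cfg)
        _, cv2 = train_classifier(table, table.class_id, cfg)
        pd.testing.assert_frame_equal(cv1, cv2)

    def test_zero_variance_predictor_dropped(self):
        table = separable_table(100)
        table["flat"] = 1.0
        cfg = ModelConfig(predictors=["f1", "f2", "flat"], cv_folds=5, seed=0)
        model, _ = train_classifier(table, table.class_id, cfg)
        assert "flat" not in model.feature_names_in_

    def test_evaluate_on_train_bounds_cv(self):
        table = separable_table(100, seed=6)
        cfg = ModelConfig(predictors=["f1", "f2"], cv_folds=5, seed=0)
        model, cv = train_classifier(table, table.class_id, cfg)
        rep = evaluate_classifier(model, table, table.class_id)
        assert rep.accuracy >= cv.accuracy.mean() - 1e-12

    def test_evaluate_rejects_empty_and_mismatched_schema(self):
        table = separable_table(100)
        cfg = ModelConfig(predictors=["f1", "f2"], cv_folds=5, seed=0)
        model, _ = train_classifier(table, table.class_id, cfg, with_cv=False)
        with pytest.raises(ValueError, match="empty"):
            evaluate_classifier(model, table.iloc[:0], [])
        with pytest.raises(ValueError, match="missing trained predictors"):
            evaluate_classifier(model, table[["f1"]], table.class_id)


class TestRegressor:
    def make_table(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame({"x1": rng.uniform(0, 10, n), "x2": rng.uniform(0, 10, n)})
        t["target"] = 2.0 * t.x1 + t.x2
        return t

    def test_noiseless_learnable_map(self):
        t = self.make_table()
        cfg = ModelConfig(task="regress", predictors=["x1", "x2"], seed=0)
        _, rep, _ = train_eval_regressor(t, "target", cfg, with_cv=False)
        assert rep.r2 >= 0.99
        assert rep.rmse == pytest.approx(np.sqrt(rep.mse), rel=1e-12)

    def test_independent_target_has_no_skill(self):
        t = self.make_table(seed=1)
        rng = np.random.default_rng(2)
        t["target"] = rng.normal(0, 1, len(t))
        cfg = ModelConfig(task="regress", predictors=["x1", "x2"], seed=0)
        _, rep, _ = train_eval_regressor(t, "target", cfg, with_cv=False)
        assert rep.r2 <= 0.05

    def test_constant_target_r2_undefined(self):
        t = self.make_table(n=100)
        t["target"] = 5.0
        cfg = ModelConfig(task="regress", predictors=["x1", "x2"], seed=0)
        _, rep, _ = train_eval_regressor(t, "target", cfg, with_cv=False)
        assert np.isnan(rep.r2)

    def test_too_few_rows_rejected(self):
        cfg = ModelConfig(task="regress", predictors=["x1", "x2"])
        with pytest.raises(ValueError, match="20 rows"):
            train_eval_regressor(self.make_table(n=10), "target", cfg)


class TestAttribution:
    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({c: rng.normal(0, 1, 800) for c in ("a", "b", "c")})
        t["target"] = 3.0 * t.a
        cfg = ModelConfig(task="regress", predictors=["a", "b", "c"], seed=0)
        model, _, _ = train_eval_regressor(t, "target", cfg, with_cv=False)
        att = feature_attribution(model, t, t.target, seed=0)
        assert att.feature.iloc[0] == "a"
        assert (att["method"] == "permutation").all()

    def test_duplicate_columns_split_importance(self):
        # permuting one copy leaves the twin intact, so each copy carries
        # a comparable share and neither reaches the lone-column value
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"a": rng.normal(0, 1, 1000), "b": rng.normal(0, 1, 1000)})
        t["a_copy"] = t.a
        t["target"] = 2.0 * t.a + 0.5 * t.b
        cfg = ModelConfig(task="regress", predictors=["a", "a_copy", "b"], seed=0)
        model, _, _ = train_eval_regressor(t, "target", cfg, with_cv=False)
        att = feature_attribution(model, t, t.target, seed=0).set_index("feature")
        cfg1 = ModelConfig(task="regress", predictors=["a", "b"], seed=0)
        model1, _, _ = train_eval_regressor(t, "target", cfg1, with_cv=False)
        lone = feature_attribution(model1, t, t.target, seed=0).set_index("feature")
        copies = att.loc[["a", "a_copy"], "importance"]
        assert (copies > att.loc["b", "importance"]).all()  # both clearly used
        assert copies.max() < lone.loc["a", "importance"]
        assert copies.min() > 0.3 * copies.max()  # split, not monopolized

    def test_unfitted_model_rejected(self):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        with pytest.raises(ValueError, match="not fitted"):
            feature_attribution(Pipeline([("s", StandardScaler())]), pd.DataFrame(), target=[1])


class TestRunExperiment:
    def test_separable_pair_is_perfect(self, cohort_small):
        table = cohort_small.copy()
        # make classes 0/1 trivially separable on one descriptor
        table.loc[table.class_id == 0, "area_um2"] = 100.0
        table.loc[table.class_id == 1, "area_um2"] = 10000.0
        bundle = run_experiment(
            table, "classify_pair", ModelConfig(cv_folds=3, seed=0), pair=(0, 1), with_cv=False
        )
        assert bundle["report"].accuracy == 1.0

    def test_supertile_synthetic_split_bundle(self, cohort_small):
        bundle = run_experiment(
            cohort_small,
            "classify_all",
            ModelConfig(seed=0),
            source="supertiles",
            eval_on="synthetic_split",
            tile_params=SuperTileParams(t=5, s=5, seed=0),
            with_cv=False,
        )
        assert bundle["eval_on"] == "synthetic_split"
        assert 0.0 <= bundle["report"].accuracy <= 1.0

    def test_original_holdout_trains_without_test_rows(self, cohort_small):
        bundle = run_experiment(
            cohort_small,
            "classify_all",
            ModelConfig(seed=1),
            source="supertiles",
            eval_on="original_holdout",
            tile_params=SuperTileParams(t=4, s=5, seed=1),
            with_cv=False,
        )
        # tiles are built from the 70% training rows only
        assert bundle["n_test_original"] == round(0.3 * len(cohort_small))

    def test_unknown_modes_rejected(self, cohort_small):
        with pytest.raises(ValueError, match="protocol"):
            run_experiment(cohort_small, "classify_some", ModelConfig())
        with pytest.raises(ValueError, match="tile_params"):
            run_experiment(cohort_small, "classify_all", ModelConfig(), source="supertiles")
        with pytest.raises(ValueError, match="eval_on"):
            run_experiment(
                cohort_small, "classify_all", ModelConfig(), source="supertiles",
                eval_on="elsewhere", tile_params=SuperTileParams(t=2, s=1),
            )
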
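"""Splitting, training, evaluation metrics and rater agreement."""

import numpy as np
import pandas as pd
import pytest

from slskit import (
    ConfigError,
    SplitSpec,
    evaluate,
    stratified_split,
    train_all,
    weighted_kappa,
)
from slskit.features import FEATURE_NAMES, ID_COLUMN, LABEL_COLUMN
from slskit.modeling import (
    CLASSIFIER_NAMES,
    confusion_counts,
    make_classifier,
    metrics_from_confusion,
)

from conftest import make_peak_table, oracle_weighted_kappa


def separable_table(n_per_class=12, seed=0, gap=50.0):
    """Three linearly separable clusters in the first two feature columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(3):
        X = rng.normal(0, 1, size=(n_per_class, len(FEATURE_NAMES)))
        X[:, 0] += gap * c
        X[:, 1] -= gap * c
        for i, x in enumerate(X):
            rows.append([f"P{c}_{i}", *x, c])
    return pd.DataFrame(rows, columns=[ID_COLUMN, *FEATURE_NAMES, LABEL_COLUMN])


class TestStratifiedSplit:
    def test_study_sized_split_is_73_32(self, peak_table):
        train, test = stratified_split(peak_table, SplitSpec(test_fraction=0.30, seed=0))
        assert len(train) == 73 and len(test) == 32

    def test_exact_stratification_small(self):
        table = separable_table(n_per_class=5)
        table = table[table[LABEL_COLUMN] < 2].reset_index(drop=True)
        train, test = stratified_split(table, SplitSpec(test_fraction=0.2, seed=1))
        counts = test[LABEL_COLUMN].value_counts()
        assert counts[0] == 1 and counts[1] == 1

    def test_deterministic_membership(self, peak_table):
        a_train, a_test = stratified_split(peak_table, SplitSpec(seed=4))
        b_train, b_test = stratified_split(peak_table, SplitSpec(seed=4))
        assert a_train[ID_COLUMN].tolist() == b_train[ID_COLUMN].tolist()
        assert a_test[ID_COLUMN].tolist() == b_test[ID_COLUMN].tolist()
        assert not set(a_train[ID_COLUMN]) & set(a_test[ID_COLUMN])

    def test_single_member_class_rejected(self):
        table = separable_table(n_per_class=4)
        table = pd.concat([table[table[LABEL_COLUMN] != 2], table[table[LABEL_COLUMN] == 2].head(1)])
        with pytest.raises(ConfigError):
            stratified_split(table.reset_index(drop=True), SplitSpec())


class TestTrainAll:
    small_grids = {
        "logistic_regression": {"model__C": [1.0]},
        "svm": {"model__C": [1.0]},
        "knn": {"model__n_neighbors": [3]},
        "random_forest": {"n_estimators": [50]},
        "gradient_boosting": {"n_estimators": [50]},
        "lightgbm": {"n_estimators": [50]},
        "adaboost": {"n_estimators": [50]},
    }

    def test_separable_data_every_classifier_near_perfect(self):
        """On linearly separable classes all seven models reach high CV F1."""
        table = separable_table(n_per_class=15)
        fitted = train_all(
            table, list(FEATURE_NAMES[:2]), grids=self.small_grids, folds=5, seed=0
        )
        assert set(fitted) == set(CLASSIFIER_NAMES)
        for name, search in fitted.items():
            assert search.best_score_ > 0.95, name

    def test_single_configuration_degenerates_to_plain_cv(self, peak_table):
        fitted = train_all(
            peak_table,
            ["knee", "summated"],
            grids={"knn": {"model__n_neighbors": [5]}},
            classifiers=["knn"],
            seed=0,
        )
        assert fitted["knn"].best_params_ == {"model__n_neighbors": 5}

    def test_invalid_grid_entry_named(self, peak_table):
        with pytest.raises(ConfigError, match="bogus"):
            train_all(
                peak_table,
                ["knee"],
                grids={"knn": {"bogus": [1]}},
                classifiers=["knn"],
            )

    def test_scaler_fitted_inside_folds_only(self):
        """An extreme outlier confined to one CV fold must not shift the
        standardization used when that fold is held out."""
        from sklearn.base import clone
        from sklearn.model_selection import StratifiedKFold, cross_validate

        table = separable_table(n_per_class=10, seed=3)
        X = table[list(FEATURE_NAMES[:2])].to_numpy()
        y = table[LABEL_COLUMN].to_numpy()
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        pipe = make_classifier("logistic_regression", seed=0)
        folds = list(cv.split(X, y))
        train0, test0 = folds[0]
        X_dirty = X.copy()
        X_dirty[test0[0], 0] = 1e6  # outlier confined to fold 0's held-out rows
        res = cross_validate(pipe, X_dirty, y, cv=cv, return_estimator=True)
        scaler0 = res["estimator"][0].named_steps["scale"]
        clean = clone(pipe).fit(X[train0], y[train0]).named_steps["scale"]
        np.testing.assert_allclose(scaler0.mean_, clean.mean_)
        assert abs(scaler0.mean_[0]) < 1e3  # the outlier never leaked in


class TestEvaluate:
    def test_perfect_predictor(self):
        table = separable_table(n_per_class=10)

        class Oracle:
            classes_ = [0, 1, 2]

            def predict(self, X):
                return np.argmax(self.predict_proba(X), axis=1)

            def predict_proba(self, X):
                p = np.zeros((len(X), 3))
                p[X[:, 0] < 25, 0] = 1
                p[(X[:, 0] >= 25) & (X[:, 0] < 75), 1] = 1
                p[X[:, 0] >= 75, 2] = 1
                return p

        report = evaluate(Oracle(), table, list(FEATURE_NAMES[:2]), name="oracle")
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        assert report.auc_ovr_macro == 1.0
        assert np.all(np.diag(report.confusion_matrix) == 10)

    def test_random_scores_give_chance_auc(self, rng):
        y = rng.integers(0, 3, 3000)
        scores = rng.uniform(size=(3000, 3))
        from sklearn.metrics import roc_auc_score

        for c in range(3):
            auc = roc_auc_score((y == c).astype(int), scores[:, c])
            assert auc == pytest.approx(0.5, abs=0.05)

    def test_fixed_confusion_matrix_arithmetic(self):
        cm = np.array([[10, 2, 0], [1, 12, 3], [0, 2, 12]])
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(34 / 42)
        assert m["per_class_f1"][0] == pytest.approx(20 / 23)
        assert m["per_class_f1"][1] == pytest.approx(24 / 32)
        assert m["per_class_f1"][2] == pytest.approx(24 / 29)
        assert m["macro_f1"] == pytest.approx((20 / 23 + 24 / 32 + 24 / 29) / 3)

    def test_report_identities_on_fitted_model(self, peak_table):
        """accuracy == trace/sum and macro-F1 == mean per-class F1, recomputed
        independently from the confusion matrix."""
        train, test = stratified_split(peak_table, SplitSpec(seed=2))
        fitted = train_all(
            train, ["knee", "summated"], grids={"random_forest": {"n_estimators": [50]}},
            classifiers=["random_forest"], seed=0,
        )
        report = evaluate(fitted["random_forest"], test, ["knee", "summated"])
        cm = report.confusion_matrix
        assert report.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        m = metrics_from_confusion(cm)
        assert report.macro_f1 == pytest.approx(m["macro_f1"])
        assert 0 <= report.specificity_macro <= 1
        assert cm.sum(axis=1).tolist() == test[LABEL_COLUMN].value_counts().sort_index().tolist()

    def test_absent_test_class_warns_and_excludes_auc(self, peak_table):
        train, test = stratified_split(peak_table, SplitSpec(seed=2))
        fitted = train_all(
            train, ["knee"], grids={"knn": {"model__n_neighbors": [3]}},
            classifiers=["knn"], seed=0,
        )
        reduced = test[test[LABEL_COLUMN] != 2].reset_index(drop=True)
        with pytest.warns(UserWarning, match="absent"):
            report = evaluate(fitted["knn"], reduced, ["knee"])
        assert np.isfinite(report.auc_ovr_macro)


class TestWeightedKappa:
    def test_identical_vectors(self):
        assert weighted_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_independent_ratings_near_zero(self, rng):
        a = rng.integers(0, 3, 4000)
        b = rng.integers(0, 3, 4000)
        assert weighted_kappa(a, b) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("weighting", ["linear", "quadratic"])
    def test_matches_contingency_oracle(self, weighting):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 1, 1, 2, 2, 2]
        got = weighted_kappa(a, b, weighting=weighting)
        assert got == pytest.approx(oracle_weighted_kappa(a, b, weighting), abs=1e-12)
        if weighting == "linear":
            assert got == pytest.approx(0.625, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            weighted_kappa([], [])


def test_accuracy_nondecreasing_with_class_separation():
    """Scaling the between-class mean gaps up cannot hurt expected accuracy."""
    from slskit import GeneratorConfig, sample_peak_targets, engineer_features
    from slskit.features import build_feature_table

    def scaled_config(scale):
        cfg = GeneratorConfig()
        base = {a: np.mean([cfg.class_angle_params[c][a][0] for c in (0, 1, 2)]) for a in ("trunk", "pelvis", "knee")}
        cfg.class_angle_params = {
            c: {
                a: (base[a] + scale * (m - base[a]), s)
                for a, (m, s) in cfg.class_angle_params[c].items()
            }
            for c in (0, 1, 2)
        }
        return cfg

    mean_acc = []
    for scale in (0.5, 1.0, 2.0):
        accs = []
        for seed in range(6):
            cfg = scaled_config(scale)
            table = make_peak_table(n_per_class=(20, 20, 20), seed=seed, config=cfg)
            train, test = stratified_split(table, SplitSpec(seed=seed))
            fitted = train_all(
                train, ["knee", "summated", "trunk_x_knee"],
                grids={"random_forest": {"n_estimators": [100]}},
                classifiers=["random_forest"], seed=seed,
            )
            rep = evaluate(fitted["random_forest"], test, ["knee", "summated", "trunk_x_knee"])
            accs.append(rep.accuracy)
        mean_acc.append(np.mean(accs))
    assert mean_acc[0] <= mean_acc[1] + 0.02 <= mean_acc[2] + 0.04
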
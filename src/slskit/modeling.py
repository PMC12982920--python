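"""Classifier training, tuning and evaluation for 3-class movement quality.

Seven classical classifiers (logistic regression, SVM, k-nearest neighbors,
random forest, gradient boosting, LightGBM, AdaBoost) are tuned by grid
search under stratified k-fold cross-validation with the macro-averaged F1
score as the optimization metric. Scale-sensitive models (logistic
regression, SVM, KNN) carry a z-score standardizer inside their pipeline so
scaling statistics are fitted on training folds only; tree ensembles see raw
feature values. Held-out evaluation reports accuracy, macro-F1, macro
one-vs-rest AUC, macro sensitivity/specificity and the 3x3 confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, SchemaError
from .features import LABEL_COLUMN, feature_matrix, labels

CLASSES = (0, 1, 2)

CLASSIFIER_NAMES = (
    "logistic_regression",
    "svm",
    "knn",
    "random_forest",
    "gradient_boosting",
    "lightgbm",
    "adaboost",
)

#: Classifiers whose distance/penalty geometry needs standardized inputs.
SCALED_CLASSIFIERS = frozenset({"logistic_regression", "svm", "knn"})


@dataclass
class SplitSpec:
    test_fraction: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must lie strictly between 0 and 1")


@dataclass
class ModelReport:
    """Held-out metrics for one classifier."""

    classifier: str
    accuracy: float
    macro_f1: float
    auc_ovr_macro: float
    sensitivity_macro: float
    specificity_macro: float
    confusion_matrix: np.ndarray  # 3x3 counts, rows = true class 0,1,2
    per_class_f1: Dict[int, float]
    best_params: Dict[str, object] = field(default_factory=dict)
    cv_macro_f1: float = float("nan")

    def to_row(self) -> Dict[str, object]:
        return {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "auc_ovr_macro": self.auc_ovr_macro,
            "sensitivity_macro": self.sensitivity_macro,
            "specificity_macro": self.specificity_macro,
            "cv_macro_f1": self.cv_macro_f1,
        }


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    table: pd.DataFrame, spec: Optional[SplitSpec] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test partition preserving class proportions.

    Deterministic for a fixed seed; every participant lands in exactly one
    partition. A class with a single member cannot be stratified and raises.
    """
    spec = spec or SplitSpec()
    spec.validate()
    y = labels(table)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    singles = [c for c, n in counts.items() if n < 2]
    if singles:
        raise ConfigError(f"classes {singles} have fewer than 2 members; cannot stratify")
    train, test = train_test_split(
        table,
        test_size=spec.test_fraction,
        stratify=y,
        random_state=spec.seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# estimators and grids
# ---------------------------------------------------------------------------

def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the seven classifiers (with its scaler if needed)."""
    if name == "logistic_regression":
        est = LogisticRegression(max_iter=5000, solver="saga", random_state=seed)
    elif name == "svm":
        est = SVC(random_state=seed)  # decision_function used for class scores
    elif name == "knn":
        est = KNeighborsClassifier()
    elif name == "random_forest":
        est = RandomForestClassifier(random_state=seed)
    elif name == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed)
    elif name == "lightgbm":
        est = LGBMClassifier(random_state=seed, verbose=-1, min_child_samples=5)
    elif name == "adaboost":
        est = AdaBoostClassifier(random_state=seed)
    else:
        raise ConfigError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")
    if name in SCALED_CLASSIFIERS:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def default_grids() -> Dict[str, Dict[str, List[object]]]:
    """Hyperparameter search spaces over the published tuned dimensions."""
    tree_depth = [2, 3, 5, None]
    n_estimators = [100, 200, 400]
    learning_rate = [0.05, 0.1, 0.5, 1.0]
    return {
        "logistic_regression": {
            "model__C": [0.01, 0.1, 1, 10],
            "model__penalty": ["l1", "l2"],
        },
        "svm": {
            "model__kernel": ["linear", "rbf"],
            "model__C": [0.1, 1, 10],
        },
        "knn": {
            "model__n_neighbors": [3, 5, 7, 9],
            "model__metric": ["euclidean", "manhattan"],
        },
        "random_forest": {
            "max_depth": tree_depth,
            "n_estimators": n_estimators,
        },
        "gradient_boosting": {
            "max_depth": [2, 3, 5],
            "n_estimators": n_estimators,
            "learning_rate": learning_rate,
        },
        "lightgbm": {
            "max_depth": [2, 3, 5, -1],
            "n_estimators": n_estimators,
            "learning_rate": learning_rate,
        },
        "adaboost": {
            "n_estimators": n_estimators,
            "learning_rate": learning_rate,
        },
    }


def train_all(
    train: pd.DataFrame,
    selected: Sequence[str],
    grids: Optional[Dict[str, Dict[str, List[object]]]] = None,
    folds: int = 5,
    seed: int = 0,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
) -> Dict[str, GridSearchCV]:
    """Grid-search each classifier on the training split.

    Standardization (where used) lives inside the pipeline, so CV folds never
    leak held-out-fold statistics. The best configuration by mean CV macro-F1
    is refit on the full training split. Returns fitted GridSearchCV objects
    keyed by classifier name.
    """
    missing = [f for f in selected if f not in train.columns]
    if missing:
        raise SchemaError(f"selected features not in training table: {missing}")
    grids = grids if grids is not None else default_grids()
    X = feature_matrix(train, selected)
    y = labels(train)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fitted: Dict[str, GridSearchCV] = {}
    for name in classifiers:
        est = make_classifier(name, seed=seed)
        grid = grids.get(name, {})
        valid = est.get_params(deep=True)
        for key in grid:
            if key not in valid:
                raise ConfigError(f"grid entry {key!r} is invalid for classifier {name!r}")
        search = GridSearchCV(est, grid, scoring="f1_macro", cv=cv, refit=True, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y)
        fitted[name] = search
    return fitted


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def class_scores(model, X: np.ndarray) -> np.ndarray:
    """Per-class membership scores: predicted probabilities where available,
    otherwise one-vs-rest decision-function scores."""
    if hasattr(model, "predict_proba"):
        try:
            return np.asarray(model.predict_proba(X))
        except AttributeError:  # e.g. SVC(probability=False) inside a pipeline
            pass
    return np.asarray(model.decision_function(X))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def metrics_from_confusion(cm: np.ndarray) -> Dict[str, object]:
    """Accuracy, per-class/macro F1 and macro sensitivity/specificity from a
    3x3 confusion matrix (rows = true class)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    accuracy = np.trace(cm) / total if total else float("nan")
    per_class_f1: Dict[int, float] = {}
    recalls, tnrs = [], []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        per_class_f1[c] = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        if cm[c].sum() > 0:
            recalls.append(rec)
            tnrs.append(tn / (tn + fp) if (tn + fp) else 0.0)
    return {
        "accuracy": float(accuracy),
        "per_class_f1": per_class_f1,
        "macro_f1": float(np.mean(list(per_class_f1.values()))),
        "sensitivity_macro": float(np.mean(recalls)) if recalls else float("nan"),
        "specificity_macro": float(np.mean(tnrs)) if tnrs else float("nan"),
    }


def evaluate(
    model,
    test: pd.DataFrame,
    selected: Sequence[str],
    name: str = "model",
) -> ModelReport:
    """Score a fitted model on the held-out split.

    Macro AUC is the unweighted mean of the three one-vs-rest AUCs computed
    from class-membership scores; a class absent from the test labels has an
    undefined AUC and is excluded from the mean with a warning.
    """
    X = feature_matrix(test, selected)
    y = labels(test)
    y_pred = np.asarray(model.predict(X))
    cm = confusion_counts(y, y_pred)
    m = metrics_from_confusion(cm)

    scores = class_scores(model, X)
    present = [c for c in CLASSES if (y == c).any()]
    model_classes = list(getattr(model, "classes_", CLASSES))
    aucs = []
    for c in present:
        if (y == c).all():
            continue  # single-class test set: OvR AUC undefined
        col = model_classes.index(c) if c in model_classes else c
        aucs.append(roc_auc_score((y == c).astype(int), scores[:, col]))
    if len(aucs) < len(CLASSES):
        warnings.warn(
            "one-vs-rest AUC undefined for absent test classes; excluded from the macro mean",
            UserWarning,
            stacklevel=2,
        )
    auc = float(np.mean(aucs)) if aucs else float("nan")

    best_params = dict(getattr(model, "best_params_", {}))
    cv_f1 = float(getattr(model, "best_score_", float("nan")))
    return ModelReport(
        classifier=name,
        accuracy=m["accuracy"],
        macro_f1=m["macro_f1"],
        auc_ovr_macro=auc,
        sensitivity_macro=m["sensitivity_macro"],
        specificity_macro=m["specificity_macro"],
        confusion_matrix=cm,
        per_class_f1=m["per_class_f1"],
        best_params=best_params,
        cv_macro_f1=cv_f1,
    )


def evaluate_all(
    fitted: Dict[str, GridSearchCV], test: pd.DataFrame, selected: Sequence[str]
) -> List[ModelReport]:
    return [evaluate(model, test, selected, name=name) for name, model in fitted.items()]


def reports_table(reports: Sequence[ModelReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


# ---------------------------------------------------------------------------
# rater agreement
# ---------------------------------------------------------------------------

def weighted_kappa(
    ratings_a: Sequence[int],
    ratings_b: Sequence[int],
    weighting: str = "linear",
) -> float:
    """Weighted Cohen kappa between two ordinal rating vectors over {0,1,2}.

    ``weighting`` is "linear" (disagreement penalty proportional to grade
    distance) or "quadratic". 1 = perfect agreement, 0 = chance level.
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.size == 0 or a.shape != b.shape:
        raise ConfigError("rating vectors must be nonempty and of equal length")
    if weighting not in ("linear", "quadratic"):
        raise ConfigError("weighting must be 'linear' or 'quadratic'")
    return float(cohen_kappa_score(a, b, labels=list(CLASSES), weights=weighting))
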
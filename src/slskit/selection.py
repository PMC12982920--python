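"""Two-stage hybrid feature selection.

Stage 1 (filter): a one-way ANOVA F test per feature across the three
movement-quality classes, with Benjamini–Hochberg false-discovery-rate
correction across features; features with adjusted q below alpha pass.

Stage 2 (wrapper): recursive feature elimination driven by random-forest
impurity importance, scoring each feature count with stratified k-fold
cross-validated accuracy; the retained set is the count maximizing mean CV
accuracy, with ties broken toward fewer features.

The final set is the intersection of the two stages, keeping features that
are both statistically separable and jointly useful to a classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SchemaError
from .features import FEATURE_NAMES, LABEL_COLUMN, feature_matrix, labels

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Per-feature statistics plus the filter, wrapper and final sets."""

    stats: pd.DataFrame  # columns: feature, F, p, q, in_filter, in_wrapper, in_final
    filter_set: List[str]
    wrapper_set: List[str]
    final_set: List[str]
    cv_curve: pd.DataFrame  # columns: n_features, mean_cv_accuracy
    fallback_used: bool = False


def _canonical_order(columns: Sequence[str]) -> List[str]:
    """Registry order for known features, sorted order for any extras."""
    known = [n for n in FEATURE_NAMES if n in columns]
    extra = sorted(c for c in columns if c not in FEATURE_NAMES)
    return known + extra


def _resolve_features(table: pd.DataFrame, features: Optional[Sequence[str]]) -> List[str]:
    if features is None:
        cols = [c for c in table.columns if c in FEATURE_NAMES]
    else:
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise SchemaError(f"features not present in table: {missing}")
        cols = list(features)
    if not cols:
        raise SchemaError("no feature columns found in table")
    return _canonical_order(cols)


def anova_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """One-way ANOVA F per feature with BH step-up correction across features.

    Returns the per-feature statistics frame and the names with adjusted
    q < ``alpha``. A feature with zero within-class variance but distinct
    class means carries all its signal between classes: F is +inf, p = 0 and
    the feature is retained. A feature constant everywhere has no
    between-class signal and is never selected.
    """
    feats = _resolve_features(table, features)
    y = labels(table)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigError("ANOVA filter needs at least 2 classes present")
    if min(int((y == c).sum()) for c in classes) < 2:
        raise ConfigError("ANOVA filter needs >= 2 samples per class")

    F = np.empty(len(feats))
    p = np.empty(len(feats))
    for j, name in enumerate(feats):
        groups = [table.loc[y == c, name].to_numpy(dtype=float) for c in classes]
        means = [g.mean() for g in groups]
        within_var = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
        between = not np.allclose(means, means[0])
        if within_var == 0.0:
            if between:
                F[j], p[j] = np.inf, 0.0  # perfectly separated feature
            else:
                F[j], p[j] = 0.0, 1.0  # constant feature: no signal
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F[j], p[j] = stats.f_oneway(*groups)
        if not np.isfinite(p[j]):
            F[j], p[j] = 0.0, 1.0
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    stats_df = pd.DataFrame({"feature": feats, "F": F, "p": p, "q": q})
    stats_df["in_filter"] = stats_df["q"] < alpha
    filter_set = stats_df.loc[stats_df["in_filter"], "feature"].tolist()
    return stats_df, filter_set


def rfecv_wrapper(
    table: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 200,
) -> Tuple[List[str], pd.DataFrame]:
    """Recursive feature elimination with cross-validated accuracy scoring.

    One feature (the least important by random-forest impurity importance) is
    removed per iteration; the mean stratified CV accuracy is recorded at each
    feature count. The retained set is the subset at the count with maximal
    mean accuracy (ties favor fewer features). Call this on the training
    split only.
    """
    feats = _resolve_features(table, features)
    y = labels(table)
    class_counts = np.bincount(y)
    smallest = class_counts[class_counts > 0].min()
    if folds > smallest:
        raise ConfigError(
            f"fold count {folds} exceeds the smallest class size {smallest}"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    current = list(feats)
    subsets: Dict[int, List[str]] = {}
    curve_rows = []
    while current:
        X = feature_matrix(table, current)
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        acc = cross_val_score(rf, X, y, cv=cv, scoring="accuracy").mean()
        subsets[len(current)] = list(current)
        curve_rows.append({"n_features": len(current), "mean_cv_accuracy": acc})
        if len(current) == 1:
            break
        rf.fit(X, y)
        drop_ix = int(np.argmin(rf.feature_importances_))
        del current[drop_ix]

    curve = pd.DataFrame(curve_rows).sort_values("n_features", ignore_index=True)
    best_acc = curve["mean_cv_accuracy"].max()
    # ties -> smallest subset
    best_n = int(curve.loc[np.isclose(curve["mean_cv_accuracy"], best_acc), "n_features"].min())
    wrapper_set = subsets[best_n]
    return _canonical_order(wrapper_set), curve


def hybrid_select(
    table: pd.DataFrame,
    alpha: float = 0.05,
    folds: int = 5,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
    n_estimators: int = 200,
) -> SelectionResult:
    """Run both stages and intersect their outputs.

    An empty intersection falls back to the wrapper set with a logged warning
    (the filter then acts only as a report).
    """
    stats_df, filter_set = anova_filter(table, alpha=alpha, features=features)
    wrapper_set, curve = rfecv_wrapper(
        table, features=features, folds=folds, seed=seed, n_estimators=n_estimators
    )
    final = [f for f in _canonical_order(filter_set) if f in set(wrapper_set)]
    fallback = False
    if not final:
        warnings.warn(
            "filter and wrapper sets are disjoint; falling back to the wrapper set",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("hybrid selection: empty intersection, using wrapper set")
        final = list(wrapper_set)
        fallback = True
    stats_df = stats_df.copy()
    stats_df["in_wrapper"] = stats_df["feature"].isin(set(wrapper_set))
    stats_df["in_final"] = stats_df["feature"].isin(set(final))
    return SelectionResult(
        stats=stats_df,
        filter_set=filter_set,
        wrapper_set=wrapper_set,
        final_set=final,
        cv_curve=curve,
        fallback_used=fallback,
    )
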
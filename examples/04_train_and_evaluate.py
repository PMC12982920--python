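"""Train the seven classifiers and report held-out metrics.

Uses reduced hyperparameter grids to keep the example quick; the library
defaults sweep the full published search dimensions.
"""

from slskit import (
    GeneratorConfig,
    SplitSpec,
    evaluate_all,
    hybrid_select,
    simulate_feature_table,
    stratified_split,
    train_all,
)
from slskit.modeling import reports_table

table = simulate_feature_table(GeneratorConfig(seed=0))
train, test = stratified_split(table, SplitSpec(test_fraction=0.30, seed=0))
selection = hybrid_select(train, seed=0)

grids = {
    "logistic_regression": {"model__C": [0.1, 1]},
    "svm": {"model__C": [1, 10]},
    "knn": {"model__n_neighbors": [5, 7]},
    "random_forest": {"n_estimators": [200]},
    "gradient_boosting": {"n_estimators": [100], "learning_rate": [0.1]},
    "lightgbm": {"n_estimators": [100], "learning_rate": [0.1]},
    "adaboost": {"n_estimators": [200], "learning_rate": [0.5]},
}
fitted = train_all(train, selection.final_set, grids=grids, folds=5, seed=0)
reports = evaluate_all(fitted, test, selection.final_set)

print(reports_table(reports).round(2).to_string(index=False))
best = max(reports, key=lambda r: (r.auc_ovr_macro, r.accuracy))
print(f"\nbest by AUC: {best.classifier}")
print("confusion matrix (rows = true good/moderate/poor):")
print(best.confusion_matrix)
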
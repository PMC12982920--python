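"""Bootstrap prediction-instability curve across dataset fractions.

Instability = SD of model accuracy across stratified subsample replicates at
each fraction of the cohort; a declining curve indicates the sample size is
adequate for stable models.
"""

from slskit import GeneratorConfig, instability_curve, simulate_feature_table

table = simulate_feature_table(GeneratorConfig(seed=0))
curve = instability_curve(
    table,
    classifiers=("logistic_regression", "knn", "random_forest"),
    fractions=(0.1, 0.3, 0.5, 0.7, 0.9),
    n_boot=50,
    seed=0,
)

print(curve.table.pivot(index="fraction", columns="classifier", values="instability")
      .round(4).to_string())
print("\nmean over classifiers:")
print(curve.mean_over_classifiers().round(4).to_string())
print("\nInstability falls as the training fraction grows: beyond ~70% of the")
print("cohort, accuracy varies little across resampled training sets.")
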
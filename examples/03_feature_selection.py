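"""Hybrid feature selection: ANOVA/Benjamini-Hochberg filter + RFE wrapper.

Runs both stages on the training split of a synthetic cohort and prints the
per-feature statistics and the intersected final set.
"""

from slskit import GeneratorConfig, SplitSpec, hybrid_select, simulate_feature_table, stratified_split

table = simulate_feature_table(GeneratorConfig(seed=0))
train, _test = stratified_split(table, SplitSpec(test_fraction=0.30, seed=0))

result = hybrid_select(train, alpha=0.05, folds=5, seed=0)

print(result.stats[["feature", "F", "p", "q", "in_filter", "in_wrapper", "in_final"]]
      .round(4).to_string(index=False))
print(f"\nfilter set ({len(result.filter_set)}): q < 0.05 after BH correction")
print(f"wrapper set ({len(result.wrapper_set)}): best CV-accuracy subset of the RFE path")
print(f"final set  ({len(result.final_set)}): {', '.join(result.final_set)}")
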
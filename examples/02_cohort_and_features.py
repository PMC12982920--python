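"""Generate a study-sized cohort and build the 17-feature table.

The cohort has 28 good / 41 moderate / 36 poor participants, 3 repetitions
each; participant labels follow the poorest-repetition rule and features come
from that poorest repetition.
"""

from slskit import FEATURE_NAMES, GeneratorConfig, simulate_feature_table

table = simulate_feature_table(GeneratorConfig(seed=0))

print(f"participants: {len(table)}, features per participant: {len(FEATURE_NAMES)}")
print("class counts:", table["label"].value_counts().sort_index().to_dict())
print("\nclass means of selected features (degrees / degree-products):")
cols = ["trunk", "pelvis", "knee", "summated", "trunk_x_knee"]
print(table.groupby("label")[cols].mean().round(2).to_string())
print("\nKnee valgus and the summated angle rise steeply from good (0) to")
print("poor (2); ratio and interaction terms encode trunk-knee coordination.")
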
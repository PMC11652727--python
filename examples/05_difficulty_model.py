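"""Nested-CV difficulty model plus discriminative-feature statistics.

Builds a labelled patch cohort whose difficult areas carry coherent
oriented texture, runs the leave-one-out/3-fold nested cross-validation
random forest (SMOTE, variance filter and standardization fitted inside
each training fold), and tests the aggregated top-5 features between
difficulty groups with Bonferroni-corrected Mann-Whitney U tests.
"""

import warnings

from mammoread import radiomics
from mammoread.model import ModelConfig, nested_cv
from mammoread.stats import comparison_table, compare_discriminative_features
from mammoread.synthetic import generate_labelled_patches

warnings.filterwarnings("ignore")

patches, labels, truth = generate_labelled_patches(
    16, 8, size=64, difficulty_effect=2.0, seed=4)
print(f"cohort: {len(patches)} areas, {labels.sum()} difficult, "
      f"injected orientation {truth['orientation_deg'][0]:.0f} deg")

table = radiomics.extract_table(patches)
config = ModelConfig(tree_grid=(25, 50), bootstrap_reps=500, seed=4)
result = nested_cv(table.to_numpy(), labels, config,
                   feature_names=list(table.columns))

print(f"out-of-fold AUC {result.auc:.3f} "
      f"(95% CI {result.auc_ci[0]:.3f}-{result.auc_ci[1]:.3f}), "
      f"accuracy {result.accuracy:.3f}")
print(f"chosen tree counts across outer folds: "
      f"{sorted(set(result.chosen_trees))}")

comparisons = compare_discriminative_features(
    table.reset_index(drop=True), labels, result.top_features)
print("\ntop-5 discriminative features (easy vs difficult, "
      "median (IQR), Bonferroni-adjusted p):")
print(comparison_table(comparisons).to_string(index=False))
# An AUC well above 0.85 with Gabor features among the top-5 mirrors
# the expected signature: oriented lambda=4 texture drives difficulty.
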
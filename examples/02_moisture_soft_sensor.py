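"""Predict the moisture ratio from appearance features (soft sensing).

Builds the standard synthetic drying dataset (6 replicate trays, 594
slice-time records: six appearance features plus the planted moisture
ratio), then fits and cross-validates the two soft sensors: a PLS
regression with the component count chosen by peak Q^2, and a 20-tree
random forest.  Prints the per-fold metric table and feature importances.
"""

from drytrack.moisture import (cross_validate, feature_importance, fit_rf,
                               select_components)
from drytrack.synth import standard_regression_dataset

ds = standard_regression_dataset(seed=1)
print(f"dataset: {len(ds)} records, {ds.X.shape[1]} features")

best_n, r2_curve, q2_curve = select_components(ds, max_components=6, k=5, seed=1)
print(f"\nPLS component scan (Q^2 peaks at {best_n} components):")
for i, (r2, q2) in enumerate(zip(r2_curve, q2_curve), start=1):
    print(f"  {i} comp: R^2={r2:.4f}  Q^2={q2:.4f}")

cv = cross_validate(ds, model="rf", k=5, seed=1)
print("\n20-tree random forest, 5-fold cross-validation:")
print(cv.table().to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"pooled Q^2 = {cv.q2:.4f}")

imp = feature_importance(fit_rf(ds, n_trees=20, seed=1))
print("\nRF feature importances (sum to 1):")
print(imp.sort_values(ascending=False).to_string(float_format=lambda v: f"{v:.3f}"))
# The forest's mean CV R^2 is ~0.99 with MAE ~0.015: appearance alone
# pins down the remaining moisture.  The shape features dominate because
# shrinkage tracks water loss directly in this scene.
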
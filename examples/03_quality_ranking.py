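"""Rank drying conditions by appearance similarity to fresh fruit.

Simulates four drying conditions of graded harshness (increasing
shrinkage and browning per unit water lost), computes each group's
relative appearance change between fresh baseline and end of drying,
standardises across groups, and ranks by Euclidean distance to the fresh
reference.  PCA of the same matrix summarises which features drive the
separation.
"""

import pandas as pd

from drytrack.quality import (distance_ranking, pca_fit,
                              relative_change_table, standardize)
from drytrack.synth import (condition_ranges, ground_truth_features,
                            make_tray, simulate_ground_truth)

severities = {"Gentle": 0.1, "Mild": 0.4, "Harsh": 0.7, "Untreated": 1.0}
tables = []
for i, (name, sev) in enumerate(severities.items()):
    specs = make_tray(seed=1 + 31 * i, spec_ranges=condition_ranges(sev))
    gt = simulate_ground_truth(specs, n_frames=11)
    tables.append(ground_truth_features(gt, group_label=name,
                                        noise_sd_features=0.02, seed=1 + 7 * i))
features = pd.concat(tables, ignore_index=True)

table = relative_change_table(features, reference_label="Fresh")
z = standardize(table)
pca = pca_fit(z, n_components=3)
ranking = distance_ranking(z, reference_label="Fresh")

print("relative appearance change, end of drying vs fresh (per group):")
print(table.to_string(float_format=lambda v: f"{v:+.3f}"))
print("\nexplained variance ratios:",
      ", ".join(f"{v:.2%}" for v in pca.explained_variance_ratio))
print("\nranking by distance to fresh (smaller = more fresh-like):")
print(ranking.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# The planted harshness ordering is recovered: gentler conditions sit
# closer to the fresh reference in the standardised feature space.
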
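"""Render a synthetic drying tray and recover its features by image analysis.

Builds a 3x3 tray of green elliptical slices, renders an 11-frame
half-hourly time-lapse in which slices shrink and brown, then runs the
full extraction pipeline (HSV segmentation -> contour extraction -> grid
ID assignment -> feature measurement) and compares the extracted area
ratios and hues against the generator's analytic ground truth.
"""

import numpy as np

import drytrack as dt
from drytrack.synth import make_tray, render_sequence

specs = make_tray(n_rows=3, n_cols=3, seed=1)
frames, gt = render_sequence(specs, n_frames=11, seed=1)

records = dt.track_sequence(frames, dt.PipelineConfig())
dt.validate_records(records)
features = dt.io.features_to_frame(records)

merged = features.merge(gt, on=["slice_id", "time_index"],
                        suffixes=("_est", "_true"))
area_err = np.abs(merged["area"] / merged["area_ratio"] - 1.0).max()
hue_err = np.abs(merged["hue_est"] - merged["hue_true"]).max()

print(f"records extracted : {len(features)} ({features['valid'].sum()} valid)")
print(f"max area-ratio err: {area_err:.4f}  (fraction of true value)")
print(f"max mean-hue err  : {hue_err:.3f} hue units (0-180 scale)")
print()
print("Slice 0 trajectory (area ratio shrinks, hue drifts toward brown):")
s0 = features[features.slice_id == 0][["time_index", "hue", "area",
                                       "perimeter", "compactness"]]
print(s0.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# A clean extraction shows every record valid, area errors well under 2%
# and hue recovered to a fraction of a unit despite pixel noise.
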
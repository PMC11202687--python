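# Methods

## Problem setting

During hot-air drying, fruit slices shrink, brown and lose water. The
package treats a drying run as a time-ordered sequence of tray
photographs (half-hourly frames, slices laid out in a fixed grid) and
derives from it (i) per-slice appearance trajectories, (ii) a
vision-based estimate of the moisture ratio, and (iii) a ranking of
drying conditions by how fresh the product still looks.

## Image pipeline

**Colour space.** RGB is converted to HSV with hue computed in degrees
on the colour hexagon and stored on the halved scale [0, 180]; S and V
are scaled to [0, 255]. Degenerate pixels follow the usual conventions
(H = 0 when max = min; S = 0 when max = 0). The conversion is exact (the
round-trip back to RGB is faithful within one 8-bit count) and is
cross-checked in the tests against scikit-image's implementation.

**Segmentation.** A pixel is foreground iff H, S and V all lie inside an
inclusive window; the default (H 35–75, S 50–255, V 50–255) isolates
green slice flesh from a dark tray. Widening any window bound can only
add foreground (tested as a property). Contours are taken as the
boundaries of 8-connected components of the binary mask, which for
binary input is parameter-free and equivalent to edge-detector-based
outlines; a Canny edge map is available for visual inspection only.
Components below `min_area` (default 500 px on real-scale images, 50 px
in the small test scenes) are discarded as dust.

**Perimeter estimation.** Per-component perimeters use the 4-direction
Crofton estimate. The choice matters because compactness is quadratic in
the perimeter: naive boundary-walk estimators (unit steps plus √2 for
diagonals) systematically overestimate smooth boundaries by ~5%, which
caps the compactness of a rasterised disk near 0.90 no matter how large
it is. With the Crofton estimate, disk compactness rises through
0.968/0.992/0.995 at radii 20/50/100 toward the circle's ideal value
of 1. Near-circular blobs at small radii may measure slightly above 1;
validity checks allow a discretisation margin of `compactness_eps`
(default 0.05). The area and perimeter *ratio* features are insensitive
to the estimator, since the bias cancels between numerator and
denominator.

**Identity tracking.** Slices barely move on the tray, so identity is
positional: centroids are sorted by y (ties by x, then input order),
split into `n_rows` equal rows, each row sorted by x, and IDs assigned
row-major. The assignment is invariant to input ordering and to
translating the whole frame. A frame whose contour count does not fit
the grid (merged or missing slices) is flagged rather than guessed at: a
placeholder record per expected slice is emitted with `valid=False`. A
baseline frame that fails aborts the sequence, because every ratio
feature is anchored there.

**Record validation.** Abnormal records are flagged by three rules, each
a configurable surrogate for manual screening: apparent growth of the
area ratio beyond 1 + `tol_grow` (default 0.05 — drying slices cannot
grow, so growth means absorbed background), an area-ratio jump larger
than `jump_tol` (default 0.30) between consecutive frames of one slice
(merged/truncated contour), and compactness outside (0, 1 + ε].

**Colour aggregation.** Features use the arithmetic mean of H, S, V over
interior pixels. Hue is angular, but the default window (35–75) is far
from the 0/180 wrap, so the arithmetic mean is safe; it is *not* valid
for threshold windows crossing the wrap point.

## Moisture soft sensor

Dry-basis moisture content is M_t = (W_t − W_d)/W_d and the moisture
ratio MR = M_t/M_0, neglecting the equilibrium moisture content (the
standard simplification for high-moisture produce; the M_e field is
retained in `DryingRecord` should equilibrium data exist). MR is 1 at
the baseline weighing and approaches 0 when fully dry; 0.05 ± 0.01 is
treated as the customary safe endpoint.

Two regressors map the six appearance features to MR:

- **PLS1** with internal predictor standardisation (mean 0, sd 1), so
  predictions are invariant to affine rescaling of any feature column.
  The component count (1–6) is chosen by scanning Q² = 1 − PRESS/SS_tot
  under shuffled 5-fold cross-validation, ties resolved toward fewer
  components. Q² pools residuals over all held-out folds into a single
  PRESS rather than averaging per-fold values, which keeps it
  well-defined for small folds.
- **Random forest** with 20 trees; every other hyperparameter stays at
  the scikit-learn default and the full parameter set is frozen into the
  model metadata. Impurity importances are reported normalised to sum
  to 1.

Folds are shuffled record-level splits by default, matching the usual
protocol for such datasets; because adjacent time points of one slice
are highly correlated, record-level CV is mildly optimistic, so a
`by_slice` mode that keeps whole slices in one fold is provided. Both
R²/Q² on training data and pooled out-of-fold values are available, as
the two conventions are often conflated in reports.

## Quality ranking

Initial slice-to-slice variation would dominate a comparison of raw
end-of-drying features, so each group is summarised by the signed
fractional change (final − baseline)/baseline of each feature per slice,
averaged over the group's valid slices; the fresh reference group is all
zeros by construction. After column-wise z-scoring (population sd;
constant columns are an error, since they carry no ranking information),
groups are ranked by Euclidean distance to the reference row. Distances
are measured in the full standardised 6-feature space: full-rank PCA is
a rotation, so full-space and full-rank PC-space distances agree exactly
and truncation would only discard information (a `pc_space` option
exists for truncated distances). PCA components are ordered by explained
variance with each component's sign fixed so its largest-magnitude
loading is positive, making loading plots reproducible.

## Synthetic scenes

The generator renders trays of filled ellipses on a uniform dark
background (outside the segmentation window), with additive Gaussian
pixel noise, and emits exact analytic ground truth per slice and frame.
Planted kinetics are first-order drying, MR(t) = exp(−k·t), with k drawn
per slice from 0.26–0.34 per half-hour step so that MR ≈ 0.05 after ten
steps (300 min). Shrinkage and browning are *coupled* to the drying
rate, as they are physically: semi-axes contract by exp(−c_a·k) per step
(so the area ratio equals MR^(2·c_a)), and hue/saturation/value drift
linearly at rates proportional to k. Slices start green (hue 52–62) and
stay inside the segmentation window across the default 11 frames; a
`hue_floor` guard can be disabled to let slices brown out of the window
and exercise invalid-record handling. Ellipse ground-truth perimeters
use the Ramanujan approximation (error < 1e-4 at these aspect ratios);
its compactness is consequently constant over time under uniform
shrinkage.

Two study-condition datasets derive from this:

- the **standard regression dataset**: six replicate 3×3 trays, 11
  frames, 594 records, analytic features plus Gaussian measurement
  noise of 2% of each column's range — extraction-level error on clean
  tray images;
- **graded drying conditions** for ranking: a severity parameter in
  [0, 1] interpolates the coupling coefficients from gentle (little
  shrinkage/browning per unit water lost, as with protective
  pretreatments at low temperature) to harsh (untreated at high
  temperature), planting an unambiguous quality ordering.

What the generator does **not** emulate: slice texture (seeds, core),
lighting gradients, specular highlights, slice movement or overlap,
low-contrast slice/tray boundaries, and heteroscedastic or temporally
correlated measurement noise. Passing tests therefore demonstrate the
correctness of the algorithms under clean, well-posed imaging
conditions, not robustness to the failure modes of real photographs
(those are exactly the cases the validity flags exist for).

## Numerical choices and degenerate inputs

- Threshold windows are inclusive on both ends; HSV rasters are float64.
- ID assignment ties (equal y, then equal x) fall back to input order,
  making the sort total and deterministic.
- Constant predictor columns raise with the column named (they cannot be
  standardised); a constant response leaves R² undefined and is reported
  as NaN with a warning rather than raising.
- Fold splits, tray sampling and pixel noise all flow from explicit
  integer seeds; identical seeds give bit-identical scenes, datasets and
  CSV outputs.
- Test problem sizes (360–480 px scenes, 3–11 frames, 594-record
  datasets) are chosen so the full suite completes in seconds while
  keeping slices above the ~20 px semi-axis scale where discretisation
  error in the area ratio stays under 2%.

## Known limitations

- Positional tracking assumes slices never swap grid cells; it cannot
  recover from a slice physically moved between frames.
- The equal-rows partition requires the full grid to be detected; a
  frame with one lost slice invalidates all of that frame's records
  rather than re-identifying the survivors.
- Arithmetic hue averaging restricts threshold windows to ones that do
  not cross the hue wrap point.
- Record-level cross-validation shares slices between train and test at
  different times; use `by_slice=True` for a leakage-free assessment.
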
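"""Synthetic drying-tray scenes with exact ground truth.

Renders time-lapses of green elliptical "slices" on a dark tray that
shrink and brown over half-hourly frames, mimicking fruit slices in a hot
air dryer.  Every scene carries an analytic ground-truth table (area and
perimeter ratios, compactness, painted HSV colour, planted moisture
ratio), so segmentation, tracking, feature extraction and the downstream
regression/ranking stages can all be verified without real photographs.

Planted kinetics: each slice's semi-axes contract by a constant factor
per step (area ratio ``shrink_rate**(2t)``), hue drifts linearly toward
brown (decreasing on the 0-180 scale), and the moisture ratio follows
first-order drying ``MR(t) = exp(-k t)``.  The default rate constant
range centres on k = 0.3 per half-hour step, which brings MR to ~0.05
after ten steps (300 min) — the usual safe-moisture endpoint for tray
drying.  The generator does not emulate texture (seeds, core), lighting
gradients or motion between frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw as _skdraw

from .imaging import ImageFrame, hsv_to_rgb

__all__ = [
    "SliceSpec",
    "SpecRanges",
    "ramanujan_perimeter",
    "make_tray",
    "condition_ranges",
    "simulate_ground_truth",
    "render_sequence",
    "ground_truth_features",
    "make_regression_dataset",
    "standard_regression_dataset",
]

GT_COLUMNS = ("slice_id", "time_index", "area_ratio", "perimeter_ratio",
              "compactness", "hue", "saturation", "value", "mr")


@dataclass(frozen=True)
class SliceSpec:
    """Geometry, colour and kinetics of one synthetic slice."""

    center: tuple[float, float]          # (x, y), px
    semi_axes_0: tuple[float, float]     # (a, b) at t=0, px
    hue_0: float                         # initial hue, 0-180
    shrink_rate: float                   # per-step factor on both semi-axes
    hue_drift: float                     # hue units lost per step (browning)
    mr_decay_k: float                    # first-order MR rate, per step
    saturation: float = 200.0
    value: float = 180.0
    sat_drift: float = 0.0               # saturation units lost per step
    val_drift: float = 0.0               # value units lost per step

    def __post_init__(self) -> None:
        a, b = self.semi_axes_0
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 < self.shrink_rate <= 1.0:
            raise ValueError("shrink_rate must be in (0, 1]")
        if not 0.0 <= self.hue_0 <= 180.0:
            raise ValueError("hue_0 must be in [0, 180]")
        if self.mr_decay_k < 0:
            raise ValueError("mr_decay_k must be non-negative")

    def hue_at(self, t: int) -> float:
        return float(np.clip(self.hue_0 - self.hue_drift * t, 0.0, 180.0))

    def saturation_at(self, t: int) -> float:
        return float(np.clip(self.saturation - self.sat_drift * t, 0.0, 255.0))

    def value_at(self, t: int) -> float:
        return float(np.clip(self.value - self.val_drift * t, 0.0, 255.0))

    def semi_axes_at(self, t: int) -> tuple[float, float]:
        f = self.shrink_rate ** t
        return self.semi_axes_0[0] * f, self.semi_axes_0[1] * f

    def mr_at(self, t: int) -> float:
        return math.exp(-self.mr_decay_k * t)


@dataclass(frozen=True)
class SpecRanges:
    """Uniform sampling ranges for tray slices (the study conditions).

    Shrinkage and browning are physically driven by moisture loss, so the
    per-slice rates are coupled to the slice's drying rate constant k:
    ``shrink_rate = exp(-area_coupling * k)`` (hence area ratio =
    MR^(2*area_coupling), a smooth monotone function of the moisture
    ratio) and ``hue_drift = hue_coupling * k``.  Defaults: green slices
    (hue ~52-62) that lose ~7-14 hue units over ten half-hourly steps
    (browning but staying inside the H 35-75 segmentation window), shrink
    to roughly half their initial area by the end of drying, and dry with
    first-order rate k ~ 0.26-0.34 per step (MR ~ 0.05 at 300 min, the
    usual safe-moisture endpoint).  ``hue_floor`` caps the drift so the
    painted hue never drops below it within ``n_frames_guard`` steps; set
    it to 0 to let slices brown out of the segmentation window and
    exercise invalid-record handling (the browning crossover).
    """

    semi_axes: tuple[float, float] = (36.0, 52.0)
    hue_0: tuple[float, float] = (52.0, 62.0)
    area_coupling: tuple[float, float] = (0.09, 0.11)   # d ln(axis)/d ln(MR)
    hue_coupling: tuple[float, float] = (3.0, 4.5)      # hue units per k per step
    sat_coupling: tuple[float, float] = (3.0, 6.0)      # sat units per k per step
    val_coupling: tuple[float, float] = (5.0, 9.0)      # value units per k per step
    mr_decay_k: tuple[float, float] = (0.26, 0.34)
    saturation: tuple[float, float] = (170.0, 220.0)
    value: tuple[float, float] = (150.0, 200.0)
    jitter: float = 8.0                   # px of grid-position jitter
    hue_floor: float = 36.0
    n_frames_guard: int = 11


def condition_ranges(severity: float, base: SpecRanges | None = None) -> SpecRanges:
    """Ranges for a drying condition of given harshness.

    ``severity`` in [0, 1] interpolates from a gentle condition (little
    shrinkage or browning per unit water lost, e.g. low temperature with
    protective pretreatment) to a harsh one (strong shrinkage and
    browning, e.g. unpretreated at high temperature).  Used to plant an
    unambiguous quality ordering across groups.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    base = base or SpecRanges()
    ca = 0.06 + 0.06 * severity     # area shrinks more per unit moisture lost
    ch = 1.5 + 3.5 * severity       # browning per unit drying
    return SpecRanges(
        semi_axes=base.semi_axes,
        hue_0=base.hue_0,
        area_coupling=(ca - 0.008, ca + 0.008),
        hue_coupling=(ch, ch + 0.4),
        sat_coupling=(1.5 + 4.0 * severity, 2.0 + 4.0 * severity),
        val_coupling=(2.0 + 8.0 * severity, 3.0 + 8.0 * severity),
        mr_decay_k=base.mr_decay_k,
        saturation=base.saturation,
        value=base.value,
        jitter=base.jitter,
        hue_floor=0.0 if severity > 0.9 else base.hue_floor,
    )


def make_tray(n_rows: int = 3, n_cols: int = 3, seed: int = 0,
              spec_ranges: SpecRanges | None = None,
              image_size: tuple[int, int] = (480, 480)) -> list[SliceSpec]:
    """Sample a tray of slices on a jittered grid; deterministic per seed.

    Raises
    ------
    ValueError
        If two sampled slices could overlap (centres closer than the sum
        of their largest semi-axes).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    rng = np.random.default_rng(seed)
    r = spec_ranges or SpecRanges()
    h, w = image_size
    specs: list[SliceSpec] = []
    for i in range(n_rows):
        for j in range(n_cols):
            cy = (i + 0.5) * h / n_rows + rng.uniform(-r.jitter, r.jitter)
            cx = (j + 0.5) * w / n_cols + rng.uniform(-r.jitter, r.jitter)
            a = rng.uniform(*r.semi_axes)
            b = rng.uniform(*r.semi_axes)
            hue0 = rng.uniform(*r.hue_0)
            k = rng.uniform(*r.mr_decay_k)
            shrink = math.exp(-rng.uniform(*r.area_coupling) * k)
            drift = rng.uniform(*r.hue_coupling) * k
            if r.hue_floor > 0:
                max_drift = (hue0 - r.hue_floor) / max(r.n_frames_guard - 1, 1)
                drift = min(drift, max_drift)
            specs.append(SliceSpec(
                center=(float(cx), float(cy)),
                semi_axes_0=(float(a), float(b)),
                hue_0=float(hue0),
                shrink_rate=float(shrink),
                hue_drift=float(max(drift, 0.0)),
                mr_decay_k=float(k),
                saturation=float(rng.uniform(*r.saturation)),
                value=float(rng.uniform(*r.value)),
                sat_drift=float(rng.uniform(*r.sat_coupling) * k),
                val_drift=float(rng.uniform(*r.val_coupling) * k),
            ))
    for m, s1 in enumerate(specs):
        for s2 in specs[m + 1:]:
            d = math.hypot(s1.center[0] - s2.center[0], s1.center[1] - s2.center[1])
            if d < max(s1.semi_axes_0) + max(s2.semi_axes_0):
                raise ValueError(
                    f"overlapping slices at {s1.center} and {s2.center}; "
                    "reduce semi-axes or jitter, or enlarge the image")
    return specs


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's ellipse perimeter approximation (error < 1e-4 for the
    aspect ratios used here); the generator's perimeter convention."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def simulate_ground_truth(specs: list[SliceSpec], n_frames: int) -> pd.DataFrame:
    """Analytic per-(slice, time) ground truth, no rasterisation.

    Columns: slice_id, time_index, area_ratio, perimeter_ratio,
    compactness, hue, saturation, value, mr.  Area ratio is
    ``shrink_rate**(2t)`` (both axes contract by the same factor);
    compactness uses the Ramanujan perimeter and is therefore constant
    over time for uniform shrinkage.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rows = []
    for sid, s in enumerate(specs):
        for t in range(n_frames):
            a, b = s.semi_axes_at(t)
            p = ramanujan_perimeter(a, b)
            rows.append((sid, t,
                         s.shrink_rate ** (2 * t),
                         s.shrink_rate ** t,
                         4.0 * math.pi * (math.pi * a * b) / p ** 2,
                         s.hue_at(t), s.saturation_at(t), s.value_at(t),
                         s.mr_at(t)))
    return pd.DataFrame(rows, columns=list(GT_COLUMNS))


def render_sequence(specs: list[SliceSpec], n_frames: int = 11,
                    image_size: tuple[int, int] = (480, 480),
                    background_rgb: tuple[int, int, int] = (40, 40, 40),
                    noise_sd: float = 2.0, seed: int = 0,
                    group_label: str = "SYN") -> tuple[list[ImageFrame], pd.DataFrame]:
    """Rasterise the tray time-lapse and return frames plus ground truth.

    Each frame paints filled ellipses with the current semi-axes and hue
    (converted to RGB) over a uniform dark background that falls outside
    the foreground HSV window, then adds i.i.d. Gaussian pixel noise of
    standard deviation ``noise_sd`` (clipped back to [0, 255]).
    Bit-identical output for identical seeds.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    gt = simulate_ground_truth(specs, n_frames)
    frames: list[ImageFrame] = []
    for t in range(n_frames):
        img = np.empty((h, w, 3), dtype=np.float64)
        img[...] = background_rgb
        for s in specs:
            a, b = s.semi_axes_at(t)
            hsv = np.array([s.hue_at(t), s.saturation_at(t), s.value_at(t)])
            rgb = hsv_to_rgb(hsv[None, None, :])[0, 0]
            rr, cc = _skdraw.ellipse(s.center[1], s.center[0], b, a, shape=(h, w))
            img[rr, cc] = rgb
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        px = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        frames.append(ImageFrame(pixels=px, time_index=t, group_label=group_label))
    return frames, gt


def ground_truth_features(ground_truth: pd.DataFrame,
                          group_label: str = "SYN",
                          noise_sd_features: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Ground truth reshaped to the extraction feature-table schema.

    Useful for feeding downstream stages (ranking, regression) without
    rasterising and re-extracting.  ``noise_sd_features`` adds Gaussian
    measurement noise per column, scaled by that column's value range
    (falling back to 1% of the column mean for columns that are constant
    in the analytic truth, e.g. compactness under uniform shrinkage).
    """
    gt = ground_truth
    out = pd.DataFrame({
        "group_label": gt["group_label"] if "group_label" in gt else group_label,
        "slice_id": gt["slice_id"].to_numpy(int),
        "time_index": gt["time_index"].to_numpy(int),
        "hue": gt["hue"].to_numpy(float),
        "saturation": gt["saturation"].to_numpy(float),
        "value": gt["value"].to_numpy(float),
        "area": gt["area_ratio"].to_numpy(float),
        "perimeter": gt["perimeter_ratio"].to_numpy(float),
        "compactness": gt["compactness"].to_numpy(float),
        "valid": True,
    })
    if noise_sd_features > 0:
        rng = np.random.default_rng(seed)
        for col in ("hue", "saturation", "value", "area", "perimeter",
                    "compactness"):
            span = out[col].max() - out[col].min()
            if span <= 0:
                span = 0.01 * abs(out[col].mean()) or 1.0
            out[col] = out[col] + rng.normal(
                0.0, noise_sd_features * span, len(out))
    return out


def make_regression_dataset(ground_truth: pd.DataFrame,
                            noise_sd_features: float = 0.0,
                            seed: int = 0,
                            group_label: str = "SYN"):
    """Build a soft-sensor regression table from ground truth.

    X holds the six appearance features (hue, saturation, value, area,
    perimeter, compactness); Y is the planted moisture ratio.  Optional
    additive Gaussian feature noise with per-column standard deviation
    ``noise_sd_features`` times that column's value range (independent
    across rows and columns); the response is left noise-free.
    """
    from .moisture import RegressionDataset

    gt = ground_truth
    X = pd.DataFrame({
        "hue": gt["hue"].to_numpy(float),
        "saturation": gt["saturation"].to_numpy(float),
        "value": gt["value"].to_numpy(float),
        "area": gt["area_ratio"].to_numpy(float),
        "perimeter": gt["perimeter_ratio"].to_numpy(float),
        "compactness": gt["compactness"].to_numpy(float),
    })
    if noise_sd_features > 0:
        rng = np.random.default_rng(seed)
        for col in X.columns:
            rng_range = X[col].max() - X[col].min()
            scale = noise_sd_features * (rng_range if rng_range > 0 else 1.0)
            X[col] = X[col] + rng.normal(0.0, scale, len(X))
    meta = pd.DataFrame({
        "group_label": gt["group_label"] if "group_label" in gt else group_label,
        "slice_id": gt["slice_id"].to_numpy(int),
        "time_index": gt["time_index"].to_numpy(int),
    })
    return RegressionDataset(X=X, y=pd.Series(gt["mr"].to_numpy(float), name="mr"),
                             meta=meta)


def standard_regression_dataset(seed: int = 0, n_groups: int = 6,
                                n_frames: int = 11,
                                n_rows: int = 3, n_cols: int = 3,
                                noise_sd_features: float = 0.02):
    """The standard synthetic soft-sensor dataset: replicate trays.

    Simulates ``n_groups`` replicate trays drying under one shared
    physics (analytic ground truth, per-slice variability in size,
    colour and rate constants) and concatenates their regression rows:
    with the defaults, 6 x 9 x 11 = 594 records.  Because shrinkage and
    browning are coupled to the drying rate, the moisture ratio is a
    smooth monotone function of the hue and area features up to the
    per-slice coupling spread.  Feature noise defaults to 2% of each
    column's range, approximating extraction error on clean tray images.
    """
    from .moisture import RegressionDataset

    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    parts = []
    for g in range(n_groups):
        specs = make_tray(n_rows, n_cols, seed=seed + 101 * g + 1)
        gt = simulate_ground_truth(specs, n_frames)
        gt["group_label"] = f"G{g}"
        parts.append(make_regression_dataset(
            gt, noise_sd_features=noise_sd_features, seed=seed + 7 * g + 13))
    X = pd.concat([p.X for p in parts], ignore_index=True)
    y = pd.concat([p.y for p in parts], ignore_index=True)
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return RegressionDataset(X=X, y=y, meta=meta)
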
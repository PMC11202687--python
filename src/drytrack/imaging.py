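"""Segmentation, identity tracking and appearance-feature extraction for
tray time-lapses of drying fruit slices.

The pipeline operates on half-hourly RGB photographs of a tray holding
slices in a fixed row/column grid.  Each frame is converted to HSV,
thresholded to a foreground mask, decomposed into connected components
(one per slice), and every component is assigned a stable identifier from
its grid position.  Six appearance features are then extracted per slice
and frame: mean hue, saturation and value over the slice interior, plus
the area ratio, perimeter ratio and compactness shape factor relative to
the pre-drying baseline frame.

Scale conventions follow the common 8-bit HSV working scale: hue in
[0, 180] (degrees halved), saturation and value in [0, 255].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import feature as _skfeature
from skimage import measure as _skmeasure

__all__ = [
    "ImageFrame",
    "HSVThresholds",
    "SliceContour",
    "FeatureRecord",
    "SegmentationError",
    "IdAssignmentError",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "segment",
    "canny_edges",
    "extract_contours",
    "assign_ids",
    "color_features",
    "compactness",
    "morphology_features",
    "track_sequence",
    "validate_records",
]

#: Discretisation allowance on compactness for rasterised shapes.  A perfect
#: analytic circle has compactness exactly 1; pixelated near-circular blobs
#: measured with the Crofton perimeter estimator may exceed 1 by a small
#: margin at small radii.
COMPACTNESS_EPS = 0.05


class SegmentationError(RuntimeError):
    """Raised when the baseline frame of a sequence cannot be segmented."""


class IdAssignmentError(ValueError):
    """Raised when detected contours cannot be arranged on the expected grid."""


@dataclass(frozen=True)
class ImageFrame:
    """One RGB tray photograph within a drying time-lapse.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        8-bit RGB raster; channel values in [0, 255].
    time_index : int
        Non-negative frame index; frames are half-hourly, index 0 is the
        pre-drying baseline.
    group_label : str
        Drying-condition label, e.g. ``"60C4ULT"``.
    """

    pixels: np.ndarray
    time_index: int
    group_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RGB channel values must lie in [0, 255]")
        if self.time_index < 0:
            raise ValueError("time_index must be non-negative")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class HSVThresholds:
    """Inclusive per-channel HSV window defining the foreground.

    Hue bounds live on the halved-degree [0, 180] scale; saturation and
    value bounds on [0, 255].  Defaults are the green-slice window used for
    kiwifruit on a dark tray.
    """

    h_lo: float = 35.0
    h_hi: float = 75.0
    s_lo: float = 50.0
    s_hi: float = 255.0
    v_lo: float = 50.0
    v_hi: float = 255.0

    def __post_init__(self) -> None:
        for lo, hi, name, top in (
            (self.h_lo, self.h_hi, "hue", 180.0),
            (self.s_lo, self.s_hi, "saturation", 255.0),
            (self.v_lo, self.v_hi, "value", 255.0),
        ):
            if not 0.0 <= lo <= hi <= top:
                raise ValueError(f"invalid {name} bounds [{lo}, {hi}] (scale 0-{top})")


@dataclass
class SliceContour:
    """A single detected slice in one frame.

    ``centroid`` is (x, y) in pixel coordinates with the origin at the
    top-left corner and y increasing downward; ``boundary`` is a closed
    polygon of (x, y) boundary points; ``pixel_area`` counts interior
    pixels; ``pixel_perimeter`` is the Crofton 4-direction boundary length
    estimate in pixel units.
    """

    centroid: tuple[float, float]
    boundary: np.ndarray
    pixel_area: int
    pixel_perimeter: float
    slice_id: int | None = None
    interior: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.pixel_perimeter <= 0:
            raise ValueError("pixel_perimeter must be positive")


@dataclass
class FeatureRecord:
    """Six appearance features for one slice at one time point.

    ``area`` and ``perimeter`` are dimensionless ratios to the same slice's
    baseline frame (exactly 1 at the baseline); ``compactness`` is
    4*pi*A/P^2 computed from the current frame's raw pixel quantities.
    """

    group_label: str
    slice_id: int
    time_index: int
    hue: float
    saturation: float
    value: float
    area: float
    perimeter: float
    compactness: float
    valid: bool = True
    pixel_area: int | None = None
    pixel_perimeter: float | None = None

    FEATURE_NAMES = ("hue", "saturation", "value", "area", "perimeter", "compactness")

    def features(self) -> tuple[float, ...]:
        return (self.hue, self.saturation, self.value,
                self.area, self.perimeter, self.compactness)


# ---------------------------------------------------------------------------
# colour space

def rgb_to_hsv(frame: ImageFrame | np.ndarray) -> np.ndarray:
    """Convert an RGB raster to HSV on the [0,180]/[0,255]/[0,255] scale.

    The conversion scales RGB to [0, 1], computes hue in degrees on the
    colour hexagon (0 when max = min), saturation as (max-min)/max (0 when
    max = 0) and value as max, then maps hue to [0, 180] by halving and
    saturation/value to [0, 255].

    Returns a float64 array of shape (H, W, 3).
    """
    px = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    rgb = px.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    delta = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.zeros_like(mx)
        sel = (delta > 0) & (mx == r)
        h = np.where(sel, (g - b) / delta * 60.0, h)
        sel = (delta > 0) & (mx == g) & (mx != r)
        h = np.where(sel, (b - r) / delta * 60.0 + 120.0, h)
        sel = (delta > 0) & (mx == b) & (mx != r) & (mx != g)
        h = np.where(sel, (r - g) / delta * 60.0 + 240.0, h)
        h = np.where(h < 0, h + 360.0, h)
        s = np.where(mx > 0, delta / np.where(mx > 0, mx, 1.0), 0.0)

    out = np.empty_like(rgb)
    out[..., 0] = h / 2.0
    out[..., 1] = s * 255.0
    out[..., 2] = mx * 255.0
    return out


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse conversion: HSV on the internal scale back to 8-bit RGB."""
    hsv = np.asarray(hsv, dtype=np.float64)
    h = hsv[..., 0] * 2.0  # degrees
    s = hsv[..., 1] / 255.0
    v = hsv[..., 2] / 255.0
    c = v * s
    hp = (h % 360.0) / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    z = np.zeros_like(c)
    idx = np.floor(hp).astype(int) % 6
    r = np.choose(idx, [c, x, z, z, x, c])
    g = np.choose(idx, [x, c, c, x, z, z])
    b = np.choose(idx, [z, z, x, c, c, x])
    m = v - c
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# segmentation

def segment(hsv_raster: np.ndarray, thresholds: HSVThresholds) -> np.ndarray:
    """Threshold an HSV raster to a boolean foreground mask.

    A pixel is foreground iff all three channels fall inside their
    inclusive [lo, hi] window.
    """
    h, s, v = hsv_raster[..., 0], hsv_raster[..., 1], hsv_raster[..., 2]
    t = thresholds
    return ((h >= t.h_lo) & (h <= t.h_hi)
            & (s >= t.s_lo) & (s <= t.s_hi)
            & (v >= t.v_lo) & (v <= t.v_hi))


def canny_edges(mask: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Canny edge map of a binary mask, for visual inspection only.

    Contour quantities are measured on connected components of the mask
    itself, which is parameter-free and equivalent for binary input; this
    edge map is provided for figures and debugging.
    """
    return _skfeature.canny(mask.astype(float), sigma=sigma)


def extract_contours(mask: np.ndarray, min_area: int = 500) -> list[SliceContour]:
    """Decompose a binary mask into per-slice contours.

    Connected components are taken with 8-connectivity; components with
    fewer than ``min_area`` pixels are dropped (dust, specular spots).
    Centroids are interior-pixel means in (x, y); the perimeter is the
    Crofton 4-direction estimate, which is asymptotically unbiased for
    smooth boundaries.  Returns an empty list when nothing passes the
    filter; slice IDs are left unassigned.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _skmeasure.label(mask, connectivity=2)
    out: list[SliceContour] = []
    for region in _skmeasure.regionprops(labels):
        if region.area < min_area:
            continue
        cy, cx = region.centroid  # row, col
        perim = region.perimeter_crofton
        # closed boundary polygon in (x, y), from the sub-pixel iso-contour
        # of this component's padded image
        rimg = np.pad(region.image.astype(float), 1)
        tracks = _skmeasure.find_contours(rimg, 0.5)
        minr, minc, _, _ = region.bbox
        if tracks:
            longest = max(tracks, key=len)
            boundary = np.column_stack([
                longest[:, 1] - 1 + minc,  # x
                longest[:, 0] - 1 + minr,  # y
            ])
        else:  # pragma: no cover - label() never yields an empty region
            boundary = np.array([[cx, cy], [cx, cy]])
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        out.append(SliceContour(
            centroid=(float(cx), float(cy)),
            boundary=boundary,
            pixel_area=int(region.area),
            pixel_perimeter=float(perim),
            interior=(rows, cols),
        ))
    return out


def assign_ids(contours: list[SliceContour], n_rows: int = 3) -> list[SliceContour]:
    """Assign stable grid IDs to contours by centroid position.

    Contours are sorted by centroid y (ties broken by x, then input
    order), partitioned into ``n_rows`` equal-size rows, and each row is
    sorted by centroid x.  IDs run 0..N-1 row-major: top row first,
    leftmost slice first.  Because slices barely move during drying, the
    same physical slice receives the same ID in every frame.

    Raises
    ------
    IdAssignmentError
        If the contour count is not divisible by ``n_rows`` — the signature
        of a segmentation failure (merged or missing slices).
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    n = len(contours)
    if n == 0 or n % n_rows != 0:
        raise IdAssignmentError(
            f"{n} contours cannot form {n_rows} equal rows; "
            "segmentation failed for this frame")
    order = sorted(range(n), key=lambda i: (contours[i].centroid[1],
                                            contours[i].centroid[0], i))
    per_row = n // n_rows
    next_id = 0
    for r in range(n_rows):
        row = order[r * per_row:(r + 1) * per_row]
        row.sort(key=lambda i: (contours[i].centroid[0],
                                contours[i].centroid[1], i))
        for i in row:
            contours[i].slice_id = next_id
            next_id += 1
    return contours


def color_features(hsv_raster: np.ndarray,
                   contour: SliceContour) -> tuple[float, float, float]:
    """Mean hue, saturation and value over a contour's interior pixels.

    The arithmetic mean is safe for hue here because the foreground window
    (default 35-75) does not cross the 0/180 wrap; it is *not* valid for
    hue windows spanning the wrap point.
    """
    if contour.interior is None or len(contour.interior[0]) == 0:
        raise ValueError("contour has no interior pixels")
    rows, cols = contour.interior
    vals = hsv_raster[rows, cols, :]
    h, s, v = vals.mean(axis=0)
    return float(h), float(s), float(v)


def compactness(area: float, perimeter: float) -> float:
    """Shape factor 4*pi*A/P^2: 1 for a circle, approaching 0 for
    elongated or ragged shapes."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter ** 2


def morphology_features(contour: SliceContour,
                        baseline_contour: SliceContour) -> tuple[float, float, float]:
    """Area ratio, perimeter ratio and compactness for one slice.

    Ratios are current/baseline pixel quantities; compactness uses the
    current frame's raw area and perimeter.
    """
    if baseline_contour.pixel_area <= 0 or baseline_contour.pixel_perimeter <= 0:
        raise ValueError("baseline contour must have positive area and perimeter")
    area = contour.pixel_area / baseline_contour.pixel_area
    perimeter = contour.pixel_perimeter / baseline_contour.pixel_perimeter
    comp = compactness(contour.pixel_area, contour.pixel_perimeter)
    return float(area), float(perimeter), float(comp)


# ---------------------------------------------------------------------------
# sequence tracking

def _segment_frame(frame: ImageFrame, config) -> tuple[np.ndarray, list[SliceContour]]:
    hsv = rgb_to_hsv(frame)
    mask = segment(hsv, config.thresholds)
    contours = extract_contours(mask, min_area=config.min_area)
    return hsv, contours


def track_sequence(frames: list[ImageFrame], config=None) -> list[FeatureRecord]:
    """Run the full per-frame pipeline over a time-ordered sequence.

    Frame 0 (smallest time_index) is the pre-drying baseline supplying the
    per-slice reference area and perimeter.  Every frame is segmented,
    decomposed into contours and ID-assigned; features are emitted for
    every (slice, time) pair.  Frames whose contour count does not fit the
    grid yield placeholder records flagged invalid.  A baseline frame that
    fails segmentation aborts the sequence.

    Records are returned with provisional validity; run
    :func:`validate_records` to apply the abnormality rules.
    """
    from .config import PipelineConfig
    if config is None:
        config = PipelineConfig()
    if not frames:
        raise ValueError("empty frame sequence")
    frames = sorted(frames, key=lambda f: f.time_index)

    hsv0, contours0 = _segment_frame(frames[0], config)
    try:
        assign_ids(contours0, config.n_rows)
    except IdAssignmentError as exc:
        raise SegmentationError(
            f"baseline frame (time_index={frames[0].time_index}, "
            f"group={frames[0].group_label!r}) failed segmentation: {exc}") from exc
    if config.expected_slices and len(contours0) != config.expected_slices:
        raise SegmentationError(
            f"baseline frame has {len(contours0)} slices, "
            f"expected {config.expected_slices}")
    baseline = {c.slice_id: c for c in contours0}
    n_slices = len(contours0)

    records: list[FeatureRecord] = []
    for frame in frames:
        if frame.time_index == frames[0].time_index:
            hsv, contours = hsv0, contours0
            ok = True
        else:
            hsv, contours = _segment_frame(frame, config)
            try:
                assign_ids(contours, config.n_rows)
                ok = len(contours) == n_slices
            except IdAssignmentError:
                ok = False
        if not ok:
            for sid in range(n_slices):
                records.append(FeatureRecord(
                    group_label=frame.group_label, slice_id=sid,
                    time_index=frame.time_index,
                    hue=math.nan, saturation=math.nan, value=math.nan,
                    area=math.nan, perimeter=math.nan, compactness=math.nan,
                    valid=False))
            continue
        for c in contours:
            h, s, v = color_features(hsv, c)
            area, perim, comp = morphology_features(c, baseline[c.slice_id])
            records.append(FeatureRecord(
                group_label=frame.group_label, slice_id=c.slice_id,
                time_index=frame.time_index,
                hue=h, saturation=s, value=v,
                area=area, perimeter=perim, compactness=comp,
                valid=True,
                pixel_area=c.pixel_area, pixel_perimeter=c.pixel_perimeter))
    return records


def validate_records(records: list[FeatureRecord],
                     tol_grow: float = 0.05,
                     jump_tol: float = 0.30,
                     compactness_eps: float = COMPACTNESS_EPS) -> list[FeatureRecord]:
    """Finalise validity flags on a tracked sequence.

    A record is marked invalid when any of the following holds:

    * its frame already failed grid ID assignment (flagged upstream);
    * its area ratio exceeds ``1 + tol_grow`` — slices cannot grow while
      drying, so apparent growth means background was absorbed into the
      contour;
    * its area ratio jumps by more than ``jump_tol`` from the same slice's
      previous frame — a merged or truncated contour;
    * its compactness falls outside ``(0, 1 + compactness_eps]``.

    These rules are a declared surrogate for manual abnormal-record
    screening; both tolerances are configurable.
    """
    by_slice: dict[tuple[str, int], list[FeatureRecord]] = {}
    for rec in records:
        by_slice.setdefault((rec.group_label, rec.slice_id), []).append(rec)
    for key, seq in by_slice.items():
        seq.sort(key=lambda r: r.time_index)
        prev_area = None
        for rec in seq:
            if not rec.valid or math.isnan(rec.area):
                rec.valid = False
                prev_area = None
                continue
            if rec.area > 1.0 + tol_grow:
                rec.valid = False
            if prev_area is not None and abs(rec.area - prev_area) > jump_tol:
                rec.valid = False
            if not (0.0 < rec.compactness <= 1.0 + compactness_eps):
                rec.valid = False
            prev_area = rec.area
    return records
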
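"""Unit and property tests for segmentation, tracking and features."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage import color as skcolor

import drytrack.imaging as im
from drytrack.imaging import (
    HSVThresholds,
    IdAssignmentError,
    ImageFrame,
    SegmentationError,
    SliceContour,
    assign_ids,
    color_features,
    compactness,
    extract_contours,
    hsv_to_rgb,
    morphology_features,
    rgb_to_hsv,
    segment,
    track_sequence,
    validate_records,
)

from conftest import disk_mask

rgb_pixel = st.tuples(*[st.integers(0, 255)] * 3)


# ---------------------------------------------------------------------------
# HSV conversion

@pytest.mark.parametrize("rgb, expected_hsv", [
    ((0, 255, 0), (60.0, 255.0, 255.0)),    # pure green: 120 deg / 2
    ((255, 0, 0), (0.0, 255.0, 255.0)),     # pure red
    ((0, 0, 255), (120.0, 255.0, 255.0)),   # pure blue: 240 deg / 2
    ((128, 128, 128), (0.0, 0.0, 128.0)),   # gray: hue 0 when max == min
    ((0, 0, 0), (0.0, 0.0, 0.0)),           # black: saturation 0 when max == 0
])
def test_rgb_to_hsv_reference_pixels(rgb, expected_hsv):
    px = np.array(rgb, np.uint8).reshape(1, 1, 3)
    hsv = rgb_to_hsv(px)[0, 0]
    assert hsv == pytest.approx(expected_hsv, abs=1e-9)


def test_rgb_to_hsv_matches_reference_implementation():
    """Cross-check against an independent HSV implementation."""
    rng = np.random.default_rng(0)
    px = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
    ours = rgb_to_hsv(px)
    ref = skcolor.rgb2hsv(px.astype(float) / 255.0)
    ref_scaled = np.stack([ref[..., 0] * 180.0, ref[..., 1] * 255.0,
                           ref[..., 2] * 255.0], axis=-1)
    # hue is circular: compare modulo 180
    dh = np.abs(ours[..., 0] - ref_scaled[..., 0])
    assert np.minimum(dh, 180.0 - dh).max() < 1e-6
    assert np.abs(ours[..., 1:] - ref_scaled[..., 1:]).max() < 1e-6


@given(rgb_pixel)
def test_hsv_round_trip(rgb):
    """rgb -> hsv -> rgb is faithful within 1 count per channel."""
    px = np.array(rgb, np.uint8).reshape(1, 1, 3)
    back = hsv_to_rgb(rgb_to_hsv(px))[0, 0]
    assert np.abs(back.astype(int) - np.array(rgb)).max() <= 1


# ---------------------------------------------------------------------------
# segmentation

@pytest.mark.parametrize("hsv, fg", [
    ((55, 150, 150), True),    # inside the default window
    ((35, 50, 50), True),      # window bounds are inclusive
    ((20, 150, 150), False),   # hue below window
    ((80, 150, 150), False),   # hue above window
    ((55, 20, 150), False),    # saturation too low
])
def test_segment_window(hsv, fg):
    raster = np.array(hsv, float).reshape(1, 1, 3)
    assert segment(raster, HSVThresholds())[0, 0] == fg


def test_segment_black_image_is_background():
    black = rgb_to_hsv(np.zeros((8, 8, 3), np.uint8))
    assert not segment(black, HSVThresholds()).any()


@given(st.integers(0, 2**31 - 1), st.integers(0, 20), st.integers(0, 20))
def test_mask_monotone_in_thresholds(seed, widen_h, widen_sv):
    """Widening any threshold interval never removes a foreground pixel."""
    rng = np.random.default_rng(seed)
    hsv = np.stack([rng.uniform(0, 180, (12, 12)),
                    rng.uniform(0, 255, (12, 12)),
                    rng.uniform(0, 255, (12, 12))], axis=-1)
    narrow = HSVThresholds()
    wide = HSVThresholds(
        h_lo=max(narrow.h_lo - widen_h, 0), h_hi=min(narrow.h_hi + widen_h, 180),
        s_lo=max(narrow.s_lo - widen_sv, 0), v_lo=max(narrow.v_lo - widen_sv, 0))
    assert (segment(hsv, wide) | ~segment(hsv, narrow)).all()


# ---------------------------------------------------------------------------
# contours

SQUARE10_CROFTON = 36.811657224201205  # 4-dir Crofton length of a 10x10 square


def test_extract_contours_square():
    mask = np.zeros((14, 14), bool)
    mask[2:12, 2:12] = True
    (c,) = extract_contours(mask, min_area=10)
    assert c.pixel_area == 100
    assert c.centroid == pytest.approx((6.5, 6.5))
    assert c.pixel_perimeter == pytest.approx(SQUARE10_CROFTON, rel=1e-9)
    assert np.allclose(c.boundary[0], c.boundary[-1])  # closed polygon
    assert c.slice_id is None


def test_extract_contours_empty_and_min_area():
    assert extract_contours(np.zeros((10, 10), bool), min_area=1) == []
    mask = np.zeros((10, 10), bool)
    mask[2:4, 2:4] = True  # 4 px blob
    assert extract_contours(mask, min_area=5) == []
    assert len(extract_contours(mask, min_area=4)) == 1


def test_extract_contours_disjoint_blobs():
    mask = np.zeros((20, 20), bool)
    mask[2:8, 2:8] = True
    mask[12:18, 12:18] = True
    assert len(extract_contours(mask, min_area=4)) == 2


# ---------------------------------------------------------------------------
# ID assignment

def grid_contours(order=None):
    """Nine unit contours on a perfect 3x3 grid, optionally re-ordered."""
    cs = []
    for i in range(3):
        for j in range(3):
            cs.append(SliceContour(centroid=(100.0 * j + 50, 100.0 * i + 50),
                                   boundary=np.zeros((2, 2)),
                                   pixel_area=10, pixel_perimeter=10.0))
    if order is not None:
        cs = [cs[k] for k in order]
    return cs


def test_assign_ids_row_major_grid():
    cs = assign_ids(grid_contours(), n_rows=3)
    for c in cs:
        row, col = int(c.centroid[1] // 100), int(c.centroid[0] // 100)
        assert c.slice_id == 3 * row + col
    assert sorted(c.slice_id for c in cs) == list(range(9))


@given(st.permutations(list(range(9))))
def test_assign_ids_permutation_invariant(order):
    ref = {c.centroid: c.slice_id for c in assign_ids(grid_contours(), 3)}
    shuffled = assign_ids(grid_contours(order), 3)
    assert {c.centroid: c.slice_id for c in shuffled} == ref


def test_assign_ids_single_contour():
    (c,) = assign_ids(grid_contours()[:1], n_rows=1)
    assert c.slice_id == 0


def test_assign_ids_wrong_count_raises():
    with pytest.raises(IdAssignmentError):
        assign_ids(grid_contours()[:8], n_rows=3)


# ---------------------------------------------------------------------------
# features

def test_color_features_mean_of_interior():
    hsv = np.zeros((4, 4, 3))
    hsv[..., :] = (60.0, 200.0, 180.0)
    hsv[2:, :, 0] = 70.0
    hsv[:2, :, 0] = 50.0
    rows, cols = np.mgrid[0:4, 0:4]
    c = SliceContour(centroid=(1.5, 1.5), boundary=np.zeros((2, 2)),
                     pixel_area=16, pixel_perimeter=12.0,
                     interior=(rows.ravel(), cols.ravel()))
    h, s, v = color_features(hsv, c)
    assert (h, s, v) == pytest.approx((60.0, 200.0, 180.0))


def test_compactness_analytic_circle_and_square():
    r, s = 3.7, 2.5
    assert compactness(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0, abs=1e-12)
    assert compactness(s * s, 4 * s) == pytest.approx(math.pi / 4, abs=1e-12)


def test_morphology_features_baseline_is_unity():
    mask = disk_mask(20)
    (c,) = extract_contours(mask, min_area=10)
    c.slice_id = 0
    area, perim, comp = morphology_features(c, c)
    assert area == 1.0 and perim == 1.0
    assert 0 < comp <= 1 + im.COMPACTNESS_EPS


def test_disk_compactness_converges_to_one():
    """Rasterised disks approach the circle's ideal compactness of 1."""
    values = []
    for r in (20, 50, 100):
        (c,) = extract_contours(disk_mask(r), min_area=10)
        values.append(compactness(c.pixel_area, c.pixel_perimeter))
    assert values[0] < values[1] < values[2] < 1.0 + 1e-9
    assert abs(values[-1] - 1.0) < 0.05


# ---------------------------------------------------------------------------
# sequence tracking

def test_track_sequence_counts_and_monotone_area(small_scene, small_config,
                                                 small_records):
    _, frames, _ = small_scene
    recs = small_records
    assert len(recs) == 27  # 9 slices x 3 frames
    per_frame = {}
    for r in recs:
        per_frame.setdefault(r.time_index, []).append(r)
    assert all(len(v) == 9 for v in per_frame.values())
    by_slice = {}
    for r in recs:
        by_slice.setdefault(r.slice_id, []).append(r)
    for sid, seq in by_slice.items():
        seq.sort(key=lambda r: r.time_index)
        areas = [r.area for r in seq]
        assert areas[0] == 1.0
        assert all(a1 > a2 for a1, a2 in zip(areas, areas[1:]))
        assert seq[0].perimeter == 1.0


def test_track_sequence_single_frame(small_scene, small_config):
    _, frames, _ = small_scene
    recs = track_sequence(frames[:1], small_config)
    assert len(recs) == 9
    assert all(r.area == 1.0 and r.perimeter == 1.0 for r in recs)


def test_track_sequence_flags_frame_with_missing_slice(small_scene, small_config):
    specs, frames, _ = small_scene
    broken = list(frames)
    px = frames[2].pixels.copy()
    x, y = specs[4].center  # paint background over the centre slice
    px[int(y) - 45:int(y) + 45, int(x) - 45:int(x) + 45] = 40
    broken[2] = ImageFrame(pixels=px, time_index=frames[2].time_index,
                           group_label=frames[2].group_label)
    recs = validate_records(track_sequence(broken, small_config))
    bad = [r for r in recs if r.time_index == 2]
    good = [r for r in recs if r.time_index != 2]
    assert len(bad) == 9 and not any(r.valid for r in bad)
    assert all(r.valid for r in good)


def test_track_sequence_baseline_failure_aborts(small_config):
    dark = ImageFrame(pixels=np.zeros((60, 60, 3), np.uint8), time_index=0)
    with pytest.raises(SegmentationError):
        track_sequence([dark], small_config)


def test_translation_invariance(small_scene, small_config):
    """Shifting every frame by a constant offset changes no feature."""
    _, frames, _ = small_scene
    shifted = [ImageFrame(pixels=np.roll(f.pixels, (7, 5), axis=(0, 1)),
                          time_index=f.time_index, group_label=f.group_label)
               for f in frames]
    a = track_sequence(frames, small_config)
    b = track_sequence(shifted, small_config)
    for ra, rb in zip(a, b):
        assert ra.slice_id == rb.slice_id
        assert ra.features() == pytest.approx(rb.features(), abs=1e-9)


# ---------------------------------------------------------------------------
# validation rules

def rec(t, area, slice_id=0, comp=0.9, valid=True):
    return im.FeatureRecord(group_label="G", slice_id=slice_id, time_index=t,
                            hue=55.0, saturation=200.0, value=180.0,
                            area=area, perimeter=1.0, compactness=comp,
                            valid=valid)


def test_validate_records_growth_rule():
    out = validate_records([rec(0, 1.0), rec(1, 1.2)])
    assert out[0].valid and not out[1].valid


def test_validate_records_jump_rule():
    out = validate_records([rec(0, 1.0), rec(1, 0.95), rec(2, 0.45), rec(3, 0.40)])
    assert [r.valid for r in out] == [True, True, False, True]


def test_validate_records_compactness_rule():
    out = validate_records([rec(0, 1.0, comp=1.2), rec(1, 0.9, comp=0.5)])
    assert not out[0].valid and out[1].valid


def test_validate_records_clean_sequence_fully_valid(small_records):
    assert all(r.valid for r in small_records)
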
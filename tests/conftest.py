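"""Shared fixtures: small rendered drying scenes and their ground truth."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import drytrack as dt
from drytrack.synth import SpecRanges, make_tray, render_sequence

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

#: compact tray for fast tests: 3x3 slices with ~26-40 px semi-axes
SMALL_RANGES = SpecRanges(semi_axes=(26.0, 40.0), jitter=6.0)
SMALL_SIZE = (360, 360)


@pytest.fixture(scope="session")
def small_config():
    return dt.PipelineConfig(min_area=50)


@pytest.fixture(scope="session")
def small_scene():
    """3 frames of 9 shrinking, browning slices plus ground truth."""
    specs = make_tray(3, 3, seed=1, spec_ranges=SMALL_RANGES,
                      image_size=SMALL_SIZE)
    frames, gt = render_sequence(specs, n_frames=3, image_size=SMALL_SIZE,
                                 noise_sd=2.0, seed=1)
    return specs, frames, gt


@pytest.fixture(scope="session")
def small_records(small_scene, small_config):
    _, frames, _ = small_scene
    recs = dt.track_sequence(frames, small_config)
    dt.validate_records(recs)
    return recs


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
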
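"""File I/O: image manifests, frame loading and the feature CSV."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import FeatureRecord, ImageFrame

__all__ = [
    "read_manifest",
    "load_frames",
    "frames_from_dir",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
]

FEATURE_CSV_COLUMNS = ("group_label", "slice_id", "time_index",
                       "hue", "saturation", "value",
                       "area", "perimeter", "compactness", "valid")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a frame manifest CSV (columns: path, time_index, group_label).

    Relative image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"path", "time_index", "group_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks column(s): {sorted(missing)}")
    df["path"] = [str((path.parent / p)) if not Path(p).is_absolute() else str(p)
                  for p in df["path"]]
    return df.sort_values(["group_label", "time_index"]).reset_index(drop=True)


def _read_rgb(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    img = iio.imread(p)
    if img.ndim == 2:  # grayscale -> replicate
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    return img


def load_frames(manifest: pd.DataFrame) -> list[ImageFrame]:
    """Load every image referenced by a manifest as an :class:`ImageFrame`."""
    return [ImageFrame(pixels=_read_rgb(row["path"]),
                       time_index=int(row["time_index"]),
                       group_label=str(row["group_label"]))
            for _, row in manifest.iterrows()]


def frames_from_dir(directory: str | Path, group_label: str = "") -> list[ImageFrame]:
    """Load all PNG/JPEG/TIFF images in a directory, time-ordered by
    lexicographic filename sort."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in {".png", ".jpg", ".jpeg",
                                           ".tif", ".tiff"})
    if not paths:
        raise FileNotFoundError(f"no images found in {directory}")
    return [ImageFrame(pixels=_read_rgb(p), time_index=t, group_label=group_label)
            for t, p in enumerate(paths)]


def features_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    """Feature records as a tidy DataFrame with the canonical columns."""
    return pd.DataFrame([{
        "group_label": r.group_label, "slice_id": r.slice_id,
        "time_index": r.time_index, "hue": r.hue, "saturation": r.saturation,
        "value": r.value, "area": r.area, "perimeter": r.perimeter,
        "compactness": r.compactness, "valid": r.valid,
    } for r in records], columns=list(FEATURE_CSV_COLUMNS))


def write_features_csv(records: list[FeatureRecord] | pd.DataFrame,
                       path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else features_to_frame(records)
    df.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV {path} lacks column(s): {sorted(missing)}")
    return df
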
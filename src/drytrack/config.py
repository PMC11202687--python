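"""Pipeline configuration: one structured object, YAML round-trippable.

Defaults reproduce the reference operating settings of the kiwifruit
drying study the pipeline was built around: green-slice HSV window
H 35-75 / S 50-255 / V 50-255, a 3x3 tray grid, 5-fold cross-validation
and a 20-tree random forest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .imaging import COMPACTNESS_EPS, HSVThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the extraction + modelling + ranking pipeline."""

    thresholds: HSVThresholds = field(default_factory=HSVThresholds)
    n_rows: int = 3
    expected_slices: int = 9
    min_area: int = 500        # px; drop components smaller than this
    tol_grow: float = 0.05     # max allowed apparent growth of area ratio
    jump_tol: float = 0.30     # max allowed area-ratio jump between frames
    compactness_eps: float = COMPACTNESS_EPS
    cv_folds: int = 5
    cv_seed: int = 0
    cv_by_slice: bool = False  # group folds by slice identity instead of records
    rf_n_trees: int = 20
    pls_max_components: int = 6
    reference_group: str = "Fresh"

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = HSVThresholds(**self.thresholds)
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.expected_slices and self.expected_slices % self.n_rows != 0:
            raise ValueError("expected_slices must be divisible by n_rows")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.rf_n_trees < 1:
            raise ValueError("rf_n_trees must be >= 1")
        if not 1 <= self.pls_max_components <= 6:
            raise ValueError("pls_max_components must be in 1..6")
        if self.tol_grow < 0 or self.jump_tol < 0:
            raise ValueError("validation tolerances must be non-negative")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
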
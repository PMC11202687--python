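"""Appearance-quality ranking of drying conditions.

Each drying condition (group) is summarised by the relative change of
its six appearance features between the end of drying and the fresh
baseline, averaged over the group's valid slices.  The fresh reference
group is all zeros by construction.  After z-scoring the features across
groups, conditions are ranked by their Euclidean distance to the
reference row — the smaller the distance, the closer the dried product
looks to fresh fruit.  PCA of the same standardised matrix provides
scores and loadings for visual exploration; because full-rank PCA is a
rotation, full-space distances and full-rank PC-space distances agree
exactly, so truncation to a few components is an option, not a default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .moisture import FEATURES

__all__ = [
    "PCAResult",
    "relative_change",
    "relative_change_table",
    "standardize",
    "pca_fit",
    "distance_ranking",
]


@dataclass
class PCAResult:
    """PCA of the standardised relative-change matrix.

    ``scores``: per-group coordinates (rows = groups, cols = PC1..);
    ``loadings``: feature weights per component; ``explained_variance_ratio``:
    fraction of variance per component, non-increasing; ``distances``:
    optional per-group Euclidean distances to the reference group.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    distances: pd.Series | None = None


def relative_change(final: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean fractional change of each feature, final vs baseline.

    Both inputs are feature tables (columns ``group_label``, ``slice_id``,
    the six features, optional ``valid``); rows are matched on
    (group_label, slice_id) and invalid rows dropped.  For every matched
    slice the signed fractional change (final - baseline)/baseline is
    taken per feature, then averaged over the group's slices.

    Raises
    ------
    ValueError
        If a baseline feature is zero (the fractional change is undefined)
        or a group has no matched valid slices.
    """
    def _clean(df):
        out = df.copy()
        if "valid" in out:
            out = out[out["valid"].astype(bool)]
        return out.set_index(["group_label", "slice_id"])

    f = _clean(final)
    b = _clean(baseline)
    common = f.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no matching valid (group, slice) pairs")
    f = f.loc[common, list(FEATURES)].astype(float)
    b = b.loc[common, list(FEATURES)].astype(float)
    if (b == 0).any().any():
        zero_cols = [c for c in FEATURES if (b[c] == 0).any()]
        raise ValueError(f"zero baseline feature(s): {', '.join(zero_cols)}")
    rel = (f - b) / b
    per_group = rel.groupby(level="group_label").mean()
    per_group.index.name = "group_label"
    return per_group


def relative_change_table(features: pd.DataFrame,
                          reference_label: str = "Fresh") -> pd.DataFrame:
    """End-of-drying relative changes for every group, plus the reference.

    For each group in a tracked feature table, the baseline is its
    earliest frame and the final state its latest frame; the reference
    group (fresh fruit, unchanged by definition) is appended as a row of
    zeros.  Returns a groups x features matrix ready for
    :func:`standardize`.
    """
    parts = []
    for label, grp in features.groupby("group_label", sort=False):
        t0, t1 = grp["time_index"].min(), grp["time_index"].max()
        base = grp[grp["time_index"] == t0]
        fin = grp[grp["time_index"] == t1]
        parts.append(relative_change(fin, base))
    table = pd.concat(parts)
    table.loc[reference_label] = 0.0
    table.index.name = "group_label"
    return table


def standardize(records: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (population standard deviation).

    Raises on constant columns — a feature that does not vary across
    groups carries no ranking information and would divide by zero.
    """
    if len(records) < 2:
        raise ValueError("need at least two groups to standardise")
    mat = records.astype(float)
    sd = mat.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValueError(f"constant column(s): {', '.join(map(str, const))}")
    return (mat - mat.mean()) / sd


def pca_fit(matrix: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of a standardised matrix with a fixed sign convention.

    Components are ordered by decreasing explained variance; each
    component's sign is chosen so its largest-magnitude loading is
    positive, making loading plots reproducible.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows")
    X = matrix.to_numpy(float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def distance_ranking(records: pd.DataFrame,
                     reference_label: str = "Fresh",
                     pc_space: int | None = None) -> pd.DataFrame:
    """Rank groups by Euclidean distance to the reference group.

    ``records`` is the standardised relative-change matrix including the
    reference row.  Distances are measured in the full standardised
    feature space by default (rotation-invariant, no truncation loss);
    pass ``pc_space=N`` to measure them in the first N principal
    components instead.  Returns a DataFrame (group_label, distance)
    sorted ascending — the first row after the reference is the most
    fresh-like condition.
    """
    if reference_label not in records.index:
        raise ValueError(f"reference group {reference_label!r} not in records")
    mat = records
    if pc_space is not None:
        mat = pca_fit(records, n_components=pc_space).scores
    ref = mat.loc[reference_label].to_numpy(float)
    d = np.sqrt(((mat.to_numpy(float) - ref) ** 2).sum(axis=1))
    out = pd.DataFrame({"group_label": mat.index.to_numpy(),
                        "distance": d}).sort_values(
        ["distance", "group_label"], kind="stable").reset_index(drop=True)
    return out
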
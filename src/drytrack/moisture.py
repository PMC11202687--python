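"""Moisture quantities and the image-feature moisture-ratio soft sensor.

Moisture content is expressed on a dry basis, M_t = (W_t - W_d)/W_d
(g water per g dry matter), and the moisture ratio as MR = M_t/M_0 with
the equilibrium moisture content neglected — the usual simplification for
high-moisture produce.  MR runs from 1 at the start of drying toward 0.

Two regression models map the six appearance features (hue, saturation,
value, area, perimeter, compactness) to MR: PLS1 with internal predictor
standardisation, and a 20-tree random forest.  Model quality is reported
as R^2, cross-validated Q^2 = 1 - PRESS/SS_tot, MSE, RMSE and MAE, with
Q^2 computed from residuals pooled over all held-out folds (a single
PRESS), not as a mean of per-fold values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = [
    "FEATURES",
    "DryingRecord",
    "RegressionDataset",
    "EvaluationMetrics",
    "CVResult",
    "PLSModel",
    "RFModel",
    "moisture_content",
    "moisture_ratio",
    "drying_records",
    "kfold_split",
    "fit_pls",
    "select_components",
    "fit_rf",
    "feature_importance",
    "evaluate",
    "cross_validate",
]

FEATURES = ("hue", "saturation", "value", "area", "perimeter", "compactness")


# ---------------------------------------------------------------------------
# moisture quantities

def moisture_content(W_t: float, W_d: float) -> float:
    """Dry-basis moisture content (W_t - W_d)/W_d.

    ``W_t`` is the current sample weight and ``W_d`` the bone-dry weight,
    both in grams.
    """
    if W_d <= 0:
        raise ValueError("bone-dry weight W_d must be positive")
    if W_t < W_d:
        raise ValueError("current weight W_t cannot be below the bone-dry weight")
    return (W_t - W_d) / W_d


def moisture_ratio(M_t: float, M_0: float) -> float:
    """Moisture ratio M_t/M_0 (equilibrium moisture neglected)."""
    if M_0 <= 0:
        raise ValueError("initial moisture content M_0 must be positive")
    if M_t < 0:
        raise ValueError("moisture content cannot be negative")
    return M_t / M_0


@dataclass(frozen=True)
class DryingRecord:
    """Weights and derived moisture state of one sample at one time."""

    W_t: float                 # current weight, g
    W_d: float                 # bone-dry weight, g
    M_t: float                 # dry-basis moisture content
    M_0: float                 # initial dry-basis moisture content
    MR: float                  # moisture ratio
    M_e: float = 0.0           # equilibrium moisture content (neglected)
    time_index: int = 0
    group_label: str = ""


def drying_records(weights: pd.DataFrame) -> list[DryingRecord]:
    """Derive moisture content and MR from a weights table.

    ``weights`` needs columns ``W_t`` and ``W_d`` plus optional
    ``time_index`` and ``group_label``; rows are treated per group in
    time order, with M_0 taken from each group's earliest record.
    """
    df = weights.copy()
    if "time_index" not in df:
        df["time_index"] = range(len(df))
    if "group_label" not in df:
        df["group_label"] = ""
    out: list[DryingRecord] = []
    for label, grp in df.groupby("group_label", sort=False):
        grp = grp.sort_values("time_index")
        first = grp.iloc[0]
        m0 = moisture_content(float(first["W_t"]), float(first["W_d"]))
        for _, row in grp.iterrows():
            mt = moisture_content(float(row["W_t"]), float(row["W_d"]))
            out.append(DryingRecord(
                W_t=float(row["W_t"]), W_d=float(row["W_d"]),
                M_t=mt, M_0=m0, MR=moisture_ratio(mt, m0),
                time_index=int(row["time_index"]), group_label=str(label)))
    return out


# ---------------------------------------------------------------------------
# dataset

@dataclass
class RegressionDataset:
    """Soft-sensor table: X = six appearance features, y = moisture ratio.

    ``meta`` carries (group_label, slice_id, time_index) per row so folds
    can optionally respect slice identity.
    """

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if set(FEATURES) <= set(self.X.columns):
            self.X = self.X[list(FEATURES)]  # canonical column order
        elif len(self.X.columns) == 0:
            raise ValueError("X has no columns")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if len(self.X) == 0:
            raise ValueError("empty dataset")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("X contains non-finite values")
        if not np.isfinite(self.y.to_numpy()).all():
            raise ValueError("y contains non-finite values")
        if self.meta is None:
            self.meta = pd.DataFrame({
                "group_label": [""] * len(self.X),
                "slice_id": np.zeros(len(self.X), int),
                "time_index": np.arange(len(self.X)),
            })

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_features(cls, features: pd.DataFrame,
                      mr: pd.Series | np.ndarray) -> "RegressionDataset":
        """Assemble from an extraction feature table (invalid rows dropped)."""
        feats = features
        if "valid" in feats:
            keep = feats["valid"].astype(bool).to_numpy()
            feats = feats.loc[keep]
            mr = pd.Series(np.asarray(mr))[keep]
        meta_cols = [c for c in ("group_label", "slice_id", "time_index")
                     if c in feats]
        meta = feats[meta_cols].reset_index(drop=True) if meta_cols else None
        X = feats[list(FEATURES)].reset_index(drop=True).astype(float)
        y = pd.Series(np.asarray(mr, float), name="mr").reset_index(drop=True)
        return cls(X=X, y=y, meta=meta)

    @property
    def slice_groups(self) -> np.ndarray:
        """Per-row (group_label, slice_id) key for slice-aware folding."""
        return (self.meta["group_label"].astype(str) + "/"
                + self.meta["slice_id"].astype(str)).to_numpy()


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationMetrics:
    """Regression quality summary for one (y, y_hat) pair."""

    r2: float
    mse: float
    rmse: float
    mae: float
    n: int
    ss_res: float = math.nan
    ss_tot: float = math.nan
    q2: float = math.nan
    press: float = math.nan


def evaluate(y, y_hat) -> EvaluationMetrics:
    """R^2, MSE, RMSE and MAE of predictions against observations.

    A constant observation vector leaves R^2 undefined; it is reported as
    NaN with a warning rather than raising.
    """
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least two samples")
    resid = y - y_hat
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    mse = ss_res / n
    mae = float(np.mean(np.abs(resid)))
    if ss_tot == 0.0:
        warnings.warn("constant observations: R^2 is undefined", RuntimeWarning)
        r2 = math.nan
    else:
        r2 = 1.0 - ss_res / ss_tot
    return EvaluationMetrics(r2=r2, mse=mse, rmse=math.sqrt(mse), mae=mae,
                             n=n, ss_res=ss_res, ss_tot=ss_tot)


# ---------------------------------------------------------------------------
# folding

def kfold_split(dataset: RegressionDataset, k: int = 5, seed: int = 0,
                by_slice: bool = False) -> list[np.ndarray]:
    """Shuffled, near-equal, disjoint, exhaustive test folds.

    With ``by_slice=True`` whole slices (all time points of one physical
    slice) are kept in the same fold, removing the temporal leakage of
    adjacent time points of one slice straddling train and test.
    Deterministic for a given seed.
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    if not by_slice:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in kf.split(np.arange(n))]
    keys = dataset.slice_groups
    uniq = pd.unique(keys)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} slices for {k} slice-level folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    chunks = np.array_split(perm, k)
    folds = []
    for ch in chunks:
        members = set(uniq[ch])
        folds.append(np.flatnonzero([kk in members for kk in keys]))
    return folds


# ---------------------------------------------------------------------------
# models

@dataclass
class PLSModel:
    """Fitted PLS1 moisture-ratio model (predictors standardised
    internally to mean 0, sd 1)."""

    n_components: int
    estimator: PLSRegression = field(repr=False, default=None)
    feature_names: tuple[str, ...] = FEATURES

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return self.estimator.predict(X).ravel()

    @property
    def x_weights(self) -> np.ndarray:
        return self.estimator.x_weights_

    @property
    def x_loadings(self) -> np.ndarray:
        return self.estimator.x_loadings_


@dataclass
class RFModel:
    """Fitted random-forest moisture-ratio model (20 trees by default)."""

    n_trees: int
    seed: int
    estimator: RandomForestRegressor = field(repr=False, default=None)
    feature_names: tuple[str, ...] = FEATURES
    params: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return self.estimator.predict(X)


def _check_no_constant_columns(X: pd.DataFrame) -> None:
    sd = X.to_numpy(float).std(axis=0)
    bad = [c for c, s in zip(X.columns, sd) if s == 0.0]
    if bad:
        raise ValueError(f"constant predictor column(s): {', '.join(bad)}; "
                         "cannot standardise")


def fit_pls(dataset: RegressionDataset, n_components: int) -> PLSModel:
    """Fit a PLS1 regression of MR on the (standardised) features."""
    p = dataset.X.shape[1]
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in 1..{p}")
    _check_no_constant_columns(dataset.X)
    est = PLSRegression(n_components=n_components, scale=True)
    est.fit(dataset.X.to_numpy(float), dataset.y.to_numpy(float))
    return PLSModel(n_components=n_components, estimator=est,
                    feature_names=tuple(dataset.X.columns))


def select_components(dataset: RegressionDataset, max_components: int = 6,
                      k: int = 5, seed: int = 0,
                      by_slice: bool = False) -> tuple[int, np.ndarray, np.ndarray]:
    """Scan PLS component counts; return (best_n, R^2 curve, Q^2 curve).

    For each component count the training R^2 is computed on the full
    data and Q^2 = 1 - PRESS/SS_tot from k-fold cross-validation with
    residuals pooled over folds.  The best count maximises Q^2, with ties
    resolved toward fewer components.
    """
    p = dataset.X.shape[1]
    max_components = min(max_components, p)
    folds = kfold_split(dataset, k=k, seed=seed, by_slice=by_slice)
    y = dataset.y.to_numpy(float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_curve = np.empty(max_components)
    q2_curve = np.empty(max_components)
    for nc in range(1, max_components + 1):
        model = fit_pls(dataset, nc)
        r2_curve[nc - 1] = evaluate(y, model.predict(dataset.X)).r2
        press = 0.0
        for test in folds:
            train = np.setdiff1d(np.arange(len(dataset)), test)
            sub = RegressionDataset(X=dataset.X.iloc[train].reset_index(drop=True),
                                    y=dataset.y.iloc[train].reset_index(drop=True),
                                    meta=dataset.meta.iloc[train].reset_index(drop=True))
            m = fit_pls(sub, nc)
            pred = m.predict(dataset.X.iloc[test])
            press += float(np.sum((y[test] - pred) ** 2))
        q2_curve[nc - 1] = 1.0 - press / ss_tot
    best_n = int(np.argmax(q2_curve)) + 1  # argmax takes the first (smallest) max
    return best_n, r2_curve, q2_curve


def fit_rf(dataset: RegressionDataset, n_trees: int = 20, seed: int = 0) -> RFModel:
    """Fit a bootstrap-aggregated regression forest.

    All hyperparameters other than the tree count stay at library
    defaults; the full parameter set is frozen into the model metadata
    for reproducibility.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    est = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    est.fit(dataset.X.to_numpy(float), dataset.y.to_numpy(float))
    return RFModel(n_trees=n_trees, seed=seed, estimator=est,
                   params=est.get_params(), feature_names=tuple(dataset.X.columns))


def feature_importance(model: RFModel) -> pd.Series:
    """Impurity-based importances, named by feature, normalised to sum 1."""
    imp = np.asarray(model.estimator.feature_importances_, float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=list(model.feature_names), name="importance")


# ---------------------------------------------------------------------------
# cross-validated assessment

@dataclass
class CVResult:
    """k-fold assessment: per-fold metrics plus pooled summaries."""

    fold_metrics: list[EvaluationMetrics]
    q2: float                   # 1 - PRESS/SS_tot, residuals pooled over folds
    press: float
    ss_tot: float
    pooled: EvaluationMetrics   # metrics of pooled out-of-fold predictions
    pooled_predictions: np.ndarray = None

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(m, attr) for m in self.fold_metrics]))

    def sd(self, attr: str) -> float:
        return float(np.std([getattr(m, attr) for m in self.fold_metrics], ddof=1))

    def table(self) -> pd.DataFrame:
        """Per-fold metrics with mean and standard-deviation rows."""
        rows = [{"fold": i + 1, "r2": m.r2, "mae": m.mae, "rmse": m.rmse,
                 "mse": m.mse} for i, m in enumerate(self.fold_metrics)]
        rows.append({"fold": "mean", "r2": self.mean("r2"),
                     "mae": self.mean("mae"), "rmse": self.mean("rmse"),
                     "mse": self.mean("mse")})
        rows.append({"fold": "sd", "r2": self.sd("r2"), "mae": self.sd("mae"),
                     "rmse": self.sd("rmse"), "mse": self.sd("mse")})
        return pd.DataFrame(rows)


def cross_validate(dataset: RegressionDataset, model: str = "rf", k: int = 5,
                   seed: int = 0, by_slice: bool = False,
                   n_trees: int = 20, n_components: int | None = None) -> CVResult:
    """k-fold cross-validation of the PLS or RF soft sensor.

    ``model`` is ``"rf"`` or ``"pls"``; for PLS, ``n_components=None``
    selects the count by an inner Q^2 scan on each training split's data
    — pass an integer to fix it.  Returns per-fold metrics, their
    mean/sd, pooled out-of-fold metrics, and pooled Q^2.
    """
    if model not in ("rf", "pls"):
        raise ValueError("model must be 'rf' or 'pls'")
    folds = kfold_split(dataset, k=k, seed=seed, by_slice=by_slice)
    y = dataset.y.to_numpy(float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fold_metrics: list[EvaluationMetrics] = []
    pooled_pred = np.empty_like(y)
    press = 0.0
    for test in folds:
        train = np.setdiff1d(np.arange(len(dataset)), test)
        sub = RegressionDataset(X=dataset.X.iloc[train].reset_index(drop=True),
                                y=dataset.y.iloc[train].reset_index(drop=True),
                                meta=dataset.meta.iloc[train].reset_index(drop=True))
        if model == "rf":
            m = fit_rf(sub, n_trees=n_trees, seed=seed)
        else:
            nc = n_components
            if nc is None:
                nc, _, _ = select_components(sub, k=min(k, len(sub)), seed=seed)
            m = fit_pls(sub, nc)
        pred = m.predict(dataset.X.iloc[test])
        pooled_pred[test] = pred
        press += float(np.sum((y[test] - pred) ** 2))
        fold_metrics.append(evaluate(y[test], pred))
    pooled = evaluate(y, pooled_pred)
    q2 = 1.0 - press / ss_tot if ss_tot > 0 else math.nan
    pooled.q2 = q2
    pooled.press = press
    return CVResult(fold_metrics=fold_metrics, q2=q2, press=press,
                    ss_tot=ss_tot, pooled=pooled, pooled_predictions=pooled_pred)
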
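"""Random-Forest regression with a permutation null for feature selection.

A trait is regressed on one omics layer (or a combination of layers) with a
regression forest. The forest itself does not provide significance levels,
so a permutation test is wrapped around it: in each of ``n_perm``
permutations of the trait values the forest is refit and both the model's
out-of-bag R^2 and every feature's impurity importance are recorded. The
upper quantile of the null R^2 distribution gates the model, and the upper
quantile of the pooled null importance distribution thresholds individual
features. Selected subsets are then refit to quantify how much variance the
reduced predictor set explains out-of-bag.

Importance is the total decrease in node impurity (residual sum of squares)
contributed by a feature, averaged over trees and scaled per sample — the
regression forest's classical impurity measure, not permutation importance.
OOB R^2 is ``1 - MSE_oob / Var(y)``: a predictive quantity computed on
left-out (out-of-bag) samples, which may legitimately be negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datasets import AlignmentError, DegenerateInputError, OmicsDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RFParams",
    "RFResult",
    "PermutationNull",
    "SignificantSet",
    "fit_random_forest",
    "permutation_null",
    "select_significant",
    "refit_on_selection",
    "combine_layers",
]


@dataclass(frozen=True)
class RFParams:
    """Regression-forest hyperparameters.

    ``max_features`` is the number (int) or fraction (float in (0,1]) of
    candidate features per split; ``None`` uses ``floor(p/3)`` — the
    classical regression-forest default. ``min_node_size`` is the minimum
    number of samples in a leaf.
    """

    n_trees: int = 1000
    max_features: int | float | None = None
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.max_features, float) and not (0 < self.max_features <= 1):
            raise ValueError("fractional max_features must be in (0, 1]")

    def resolve_max_features(self, p: int) -> int:
        if self.max_features is None:
            return max(1, p // 3)
        if isinstance(self.max_features, float):
            return max(1, int(self.max_features * p))
        return min(max(1, int(self.max_features)), p)


@dataclass
class RFResult:
    oob_r2: float
    importance: pd.Series  # feature -> impurity-decrease score, >= 0
    params: RFParams
    layer: str = "matrix"

    def __post_init__(self) -> None:
        if self.oob_r2 > 1 + 1e-12:
            raise ValueError("OOB R^2 cannot exceed 1")


@dataclass
class PermutationNull:
    """Null distributions from permutations of the trait values."""

    n_perm: int
    null_r2: np.ndarray  # (n_perm,)
    null_importance: np.ndarray  # (n_perm, n_features)
    feature_ids: list[str]
    params: RFParams

    @property
    def null_importance_pool(self) -> np.ndarray:
        return self.null_importance.ravel()

    def r2_threshold(self, q: float) -> float:
        return float(np.quantile(self.null_r2, q))

    def importance_threshold(self, q: float, per_feature: bool = False) -> float | pd.Series:
        """Pooled (default) or per-feature quantile of the null importances."""
        if per_feature:
            vals = np.quantile(self.null_importance, q, axis=0)
            return pd.Series(vals, index=self.feature_ids)
        return float(np.quantile(self.null_importance_pool, q))


@dataclass
class SignificantSet:
    layer: str
    features: pd.DataFrame  # columns feature_id, importance, rank
    model_significant: bool
    alpha_model: float
    alpha_feature: float
    r2_threshold: float = np.nan
    importance_threshold: float = np.nan

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features["feature_id"])

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# fitting

def _as_sample_matrix(X: OmicsDataset | pd.DataFrame) -> tuple[pd.DataFrame, str]:
    if isinstance(X, OmicsDataset):
        return X.to_sample_matrix(), X.layer
    return X, "matrix"


def _align(Xs: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    if list(Xs.index) != list(y.index):
        if set(Xs.index) != set(y.index):
            raise AlignmentError("omics samples and trait samples differ")
        y = y.loc[Xs.index]
    return Xs, y


def _impute_median(Xs: pd.DataFrame) -> pd.DataFrame:
    if Xs.isna().any().any():
        med = Xs.median(axis=0)
        Xs = Xs.fillna(med).fillna(0.0)
    return Xs


def _fit_forest(
    Xv: np.ndarray, yv: np.ndarray, params: RFParams, seed: int
) -> tuple[float, np.ndarray]:
    """Fit one forest; return (oob_r2, mean unnormalized impurity decrease).

    OOB predictions are aggregated manually so that samples that are in-bag
    for every tree are simply excluded from the OOB MSE rather than
    zero-filled.
    """
    n, p = Xv.shape
    rf = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=params.resolve_max_features(p),
        min_samples_leaf=params.min_node_size,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xv, yv)

    X32 = np.ascontiguousarray(Xv, dtype=np.float32)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    importance = np.zeros(p)
    for est, inbag_idx in zip(rf.estimators_, rf.estimators_samples_):
        pred = est.tree_.predict(X32).ravel()
        mask = np.ones(n, dtype=bool)
        mask[inbag_idx] = False
        oob_sum[mask] += pred[mask]
        oob_cnt[mask] += 1
        importance += est.tree_.compute_feature_importances(normalize=False)
    importance /= len(rf.estimators_)

    seen = oob_cnt > 0
    if not seen.any():
        return float("nan"), importance
    mse = np.mean((yv[seen] - oob_sum[seen] / oob_cnt[seen]) ** 2)
    var_y = np.var(yv)
    return float(1.0 - mse / var_y), importance


def fit_random_forest(
    X: OmicsDataset | pd.DataFrame, y: pd.Series, params: RFParams | None = None
) -> RFResult:
    """Regress trait y on the feature matrix with a seeded regression forest.

    Missing omics values are imputed with the per-feature median before
    fitting. Raises on misaligned samples or a constant trait.
    """
    params = params or RFParams()
    Xs, layer = _as_sample_matrix(X)
    Xs, y = _align(Xs, y)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(y.to_numpy(dtype=float)) == 0:
        raise DegenerateInputError("trait is constant")
    Xs = _impute_median(Xs)
    oob_r2, imp = _fit_forest(
        Xs.to_numpy(dtype=float), y.to_numpy(dtype=float), params, params.seed
    )
    return RFResult(oob_r2, pd.Series(imp, index=Xs.columns), params, layer)


def permutation_null(
    X: OmicsDataset | pd.DataFrame,
    y: pd.Series,
    params: RFParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Fit forests on ``n_perm`` permutations of y (features untouched).

    Each permutation records the OOB R^2 and the full importance vector;
    thresholds are read off as quantiles of the null R^2 values and of the
    pooled importance distribution.
    """
    params = params or RFParams()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse quantile resolution; use >= 100",
            UserWarning,
            stacklevel=2,
        )
    Xs, _ = _as_sample_matrix(X)
    Xs, y = _align(Xs, y)
    Xs = _impute_median(Xs)
    Xv = Xs.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_feat = Xv.shape[1]
    null_r2 = np.empty(n_perm)
    null_imp = np.empty((n_perm, n_feat), dtype=np.float32)
    for i in range(n_perm):
        y_perm = rng.permutation(yv)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        r2, imp = _fit_forest(Xv, y_perm, params, fit_seed)
        null_r2[i] = r2
        null_imp[i] = imp
    return PermutationNull(n_perm, null_r2, null_imp, list(Xs.columns), params)


def select_significant(
    fit: RFResult,
    null: PermutationNull,
    alpha_feature: float = 0.001,
    alpha_model: float = 0.001,
    per_feature: bool = False,
) -> SignificantSet:
    """Gate the model on the null R^2 quantile, then threshold features.

    The model is significant iff its OOB R^2 exceeds the ``1 - alpha_model``
    quantile of the null R^2 distribution; only then are features selected,
    as those whose importance exceeds the ``1 - alpha_feature`` quantile of
    the pooled (or per-feature, if requested) null importances. Selected
    features are ranked by importance, descending.
    """
    if list(fit.importance.index) != null.feature_ids:
        raise ValueError("null was built on different features than the fit")
    r2_thr = null.r2_threshold(1 - alpha_model)
    imp_thr = null.importance_threshold(1 - alpha_feature, per_feature=per_feature)
    model_sig = bool(fit.oob_r2 > r2_thr)
    if model_sig:
        mask = fit.importance > imp_thr
        sel = fit.importance[mask].sort_values(ascending=False)
        features = pd.DataFrame(
            {
                "feature_id": sel.index,
                "importance": sel.to_numpy(),
                "rank": np.arange(1, len(sel) + 1),
            }
        )
    else:
        features = pd.DataFrame(columns=["feature_id", "importance", "rank"])
    layer = fit.layer
    logger.info(
        "selection: model_significant=%s oob_r2=%.3f r2_thr=%.3f (alpha_model=%g) "
        "n_selected=%d (alpha_feature=%g)",
        model_sig, fit.oob_r2, r2_thr, alpha_model, len(features), alpha_feature,
    )
    scalar_thr = imp_thr if np.isscalar(imp_thr) else float("nan")
    return SignificantSet(
        layer, features, model_sig, alpha_model, alpha_feature, r2_thr, scalar_thr
    )


def refit_on_selection(
    X: OmicsDataset | pd.DataFrame,
    selection: SignificantSet | Sequence[str],
    y: pd.Series,
    params: RFParams | None = None,
) -> RFResult:
    """Fresh forest on the matrix restricted to the selected features."""
    ids = selection.feature_ids if isinstance(selection, SignificantSet) else list(selection)
    if len(ids) == 0:
        raise ValueError("cannot refit on an empty selection")
    Xs, _ = _as_sample_matrix(X)
    missing = set(ids) - set(Xs.columns)
    if missing:
        raise KeyError(f"selected features not in matrix: {sorted(missing)[:5]}")
    return fit_random_forest(Xs[ids], y, params)


def combine_layers(
    sets: Sequence[SignificantSet], layers: Sequence[OmicsDataset]
) -> OmicsDataset:
    """Column-concatenate each layer's significant features over the sample
    intersection; feature IDs keep their layer namespaces."""
    by_name = {layer.layer: layer for layer in layers}
    pieces: list[pd.DataFrame] = []
    for s in sets:
        if len(s) == 0:
            continue
        if s.layer not in by_name:
            raise KeyError(f"no layer named {s.layer!r} supplied")
        pieces.append(by_name[s.layer].restrict(s.feature_ids).values)
    if not pieces:
        raise ValueError("all significant sets are empty")
    shared: set[str] | None = None
    for piece in pieces:
        cols = set(piece.columns)
        shared = cols if shared is None else (shared & cols)
    if not shared:
        raise AlignmentError("layers have disjoint sample sets")
    order = sorted(shared)
    stacked = pd.concat([piece[order] for piece in pieces], axis=0)
    if stacked.index.duplicated().any():
        dupes = stacked.index[stacked.index.duplicated()].unique()
        raise ValueError(f"duplicate feature IDs across layers: {list(dupes)[:5]}")
    return OmicsDataset("combined", stacked)
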
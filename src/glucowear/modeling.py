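"""Regression models under leave-one-participant-out cross-validation.

Two estimator families behind one contract: a random forest (100 trees,
max depth 16) and a LightGBM gradient-boosted tree (gbdt, 5000 leaves,
learning rate 0.1, 100 estimators, max depth 16, mse objective, bagging
fraction 0.6, feature fraction 1.0, L2 regularisation 0.9, gain importance).
Per-fold estimator seeds are master seed + fold index, so a run is fully
reproducible from one integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.ensemble import RandomForestRegressor

from .features import FeatureMatrix
from .types import ConfigError

log = logging.getLogger(__name__)

FAMILIES = ("random_forest", "gradient_boosting")

RF_DEFAULTS = {"n_estimators": 100, "max_depth": 16}
LGBM_DEFAULTS = {
    "boosting_type": "gbdt",
    "objective": "regression",
    "num_leaves": 5000,
    "learning_rate": 0.1,
    "n_estimators": 100,
    "max_depth": 16,
    "bagging_fraction": 0.6,
    "feature_fraction": 1.0,
    "reg_lambda": 0.9,
}


@dataclass
class ModelConfig:
    """Estimator family + hyperparameter overrides + master seed."""

    family: str = "random_forest"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"family must be one of {FAMILIES}")

    def resolved_params(self) -> dict:
        base = dict(RF_DEFAULTS if self.family == "random_forest"
                    else LGBM_DEFAULTS)
        base.update(self.params)
        return base


def make_estimator(config: ModelConfig, seed: int | None = None):
    seed = config.seed if seed is None else seed
    params = config.resolved_params()
    if config.family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    return LGBMRegressor(random_state=seed, n_jobs=1, verbosity=-1, **params)


def extract_importance(estimator, config: ModelConfig) -> np.ndarray:
    """MDI (forest) or total split gain (boosting), as raw non-negative scores."""
    if config.family == "random_forest":
        return np.asarray(estimator.feature_importances_, dtype=float)
    return np.asarray(
        estimator.booster_.feature_importance(importance_type="gain"),
        dtype=float)


def fit_predict(
    train: FeatureMatrix, test: FeatureMatrix, config: ModelConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on train, predict test; returns (predictions, importance vector)."""
    if len(train) == 0:
        raise ConfigError("training matrix is empty")
    if train.feature_names != test.feature_names:
        diff = set(train.feature_names) ^ set(test.feature_names)
        raise ConfigError(f"train/test feature mismatch: {sorted(diff)}")
    est = make_estimator(config, seed=seed)
    est.fit(train.X, train.y)
    return est.predict(test.X), extract_importance(est, config)


@dataclass
class Fold:
    """Held-out predictions for one participant."""

    participant_id: str
    indices: np.ndarray  # row indices in the source matrix
    y_true: np.ndarray
    y_pred: np.ndarray
    importance: np.ndarray | None = None
    feature_names: list[str] | None = None
    selection: object = None  # SelectionResult when BoRFE ran in-fold


@dataclass
class FoldPredictions:
    folds: list[Fold]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        y = np.concatenate([f.y_true for f in self.folds])
        p = np.concatenate([f.y_pred for f in self.folds])
        return y, p

    def per_fold(self, metric) -> np.ndarray:
        return np.array([metric(f.y_true, f.y_pred) for f in self.folds])

    def fold_sd(self, metric) -> float:
        """Dispersion of a metric across folds (SD over participants)."""
        return float(np.std(self.per_fold(metric), ddof=1))


def _validate_partition(matrix: FeatureMatrix, folds: list[Fold]) -> None:
    all_idx = np.concatenate([f.indices for f in folds]) if folds else np.array([])
    if len(np.unique(all_idx)) != len(all_idx) or len(all_idx) != len(matrix):
        raise ConfigError("fold indices do not partition the matrix rows")


def lopocv_predict(
    matrix: FeatureMatrix,
    config: ModelConfig,
    selection: str = "none",
    selection_kwargs: dict | None = None,
) -> FoldPredictions:
    """One fold per participant; the held-out participant never trains.

    ``selection='per_fold'`` reruns BoRFE inside each training fold (no
    selection bias); ``selection='global'`` runs it once on the full matrix
    before folding (the single-global-ranking style); ``'none'`` uses all
    features.
    """
    if selection not in ("none", "per_fold", "global"):
        raise ConfigError("selection must be 'none', 'per_fold' or 'global'")
    groups = matrix.groups
    pids = list(dict.fromkeys(groups))  # stable order of appearance
    if len(pids) < 2:
        raise ConfigError("LOPOCV needs at least 2 participants")

    from .selection import borfe_select  # deferred: selection uses this module

    base = matrix
    if selection == "global":
        sel = borfe_select(matrix, config, **(selection_kwargs or {}))
        base = matrix.restrict(sorted(sel.selected))

    folds = []
    for k, pid in enumerate(pids):
        held = groups == pid
        if held.sum() == 0:
            log.warning("participant %s has no rows; excluded", pid)
            continue
        train = base.subset_rows(~held)
        test = base.subset_rows(held)
        sel_result = None
        if selection == "per_fold":
            sel_result = borfe_select(train, config, **(selection_kwargs or {}))
            keep = sorted(sel_result.selected)
            train, test = train.restrict(keep), test.restrict(keep)
        preds, importance = fit_predict(
            train, test, config, seed=config.seed + k)
        folds.append(Fold(
            participant_id=str(pid),
            indices=np.nonzero(held)[0],
            y_true=test.y,
            y_pred=np.asarray(preds, dtype=float),
            importance=importance,
            feature_names=list(train.feature_names),
            selection=sel_result,
        ))
    out = FoldPredictions(folds=folds)
    _validate_partition(matrix, folds)
    return out


def training_mean_baseline(matrix: FeatureMatrix) -> FoldPredictions:
    """LOPOCV baseline that predicts each fold's training-set mean glucose."""
    groups = matrix.groups
    y = matrix.y
    folds = []
    for pid in dict.fromkeys(groups):
        held = groups == pid
        mean = float(y[~held].mean())
        folds.append(Fold(
            participant_id=str(pid),
            indices=np.nonzero(held)[0],
            y_true=y[held],
            y_pred=np.full(int(held.sum()), mean),
        ))
    return FoldPredictions(folds=folds)
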
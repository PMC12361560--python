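"""BoRFE: two-layer ensemble feature selection.

Layer 1 screens with Boruta: every iteration appends a shuffled "shadow" copy
of each candidate feature, fits the estimator, and scores a hit whenever a
real feature's importance beats the best shadow; features are then confirmed
or rejected by a two-sided binomial test against p = 0.5 with Bonferroni
correction, anything else staying tentative.  Layer 2 refines the survivors
with recursive feature elimination (step = 1) scored by mean RMSE under
leave-one-participant-out CV; the selected subset is the CV-optimal one
(ties prefer the smaller subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .features import FeatureMatrix
from .modeling import ModelConfig, extract_importance, make_estimator
from .types import ConfigError

log = logging.getLogger(__name__)


class NoInformativeFeatures(ConfigError):
    """Boruta confirmed nothing and no tentative features remain."""


@dataclass
class BorutaResult:
    confirmed: set[str]
    tentative: set[str]
    rejected: set[str]
    hits: dict[str, int]
    iterations: int
    alpha: float

    def __post_init__(self) -> None:
        sets = (self.confirmed, self.tentative, self.rejected)
        union = set().union(*sets)
        if sum(len(s) for s in sets) != len(union) or union != set(self.hits):
            raise ConfigError("confirmed/tentative/rejected must partition "
                              "the candidates")
        if any(h > self.iterations for h in self.hits.values()):
            raise ConfigError("hit counts cannot exceed iterations")


@dataclass
class SelectionResult:
    boruta: BorutaResult
    elimination_order: list[str]  # first eliminated first
    cv_score_per_subset: list[tuple[int, float]]  # (size, mean CV RMSE)
    selected: set[str]
    seeds: dict = field(default_factory=dict)


def boruta_screen(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    iterations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> BorutaResult:
    """All-relevant screening by shadow-feature comparison."""
    config = config or ModelConfig()
    names = list(matrix.feature_names)
    if len(names) < 2:
        raise ConfigError("Boruta needs at least 2 candidate features")
    X, y = matrix.X, matrix.y
    if X.shape[0] < 20:
        raise ConfigError("Boruta needs at least 20 rows")
    rng = np.random.default_rng(seed)
    k = len(names)
    hits = np.zeros(k, dtype=int)
    for it in range(iterations):
        shadows = rng.permuted(X, axis=0)
        try:
            est = make_estimator(config, seed=seed + it + 1)
            est.fit(np.hstack([X, shadows]), y)
        except Exception as exc:  # pragma: no cover - estimator failure path
            raise RuntimeError(f"estimator failed at Boruta iteration {it}: "
                               f"{exc}") from exc
        imp = extract_importance(est, config)
        hits += imp[:k] > imp[k:].max()

    corrected = alpha / k  # Bonferroni
    confirmed, tentative, rejected = set(), set(), set()
    for name, h in zip(names, hits):
        p_hi = binomtest(int(h), iterations, 0.5, alternative="greater").pvalue
        p_lo = binomtest(int(h), iterations, 0.5, alternative="less").pvalue
        if p_hi < corrected:
            confirmed.add(name)
        elif p_lo < corrected:
            rejected.add(name)
        else:
            tentative.add(name)
    return BorutaResult(
        confirmed=confirmed, tentative=tentative, rejected=rejected,
        hits={n: int(h) for n, h in zip(names, hits)},
        iterations=iterations, alpha=alpha,
    )


def _logo_rmse(matrix: FeatureMatrix, config: ModelConfig,
               seed: int) -> tuple[float, np.ndarray]:
    """Mean LOPOCV RMSE plus mean per-fold importance for the given features."""
    groups = matrix.groups
    pids = list(dict.fromkeys(groups))
    if len(pids) < 2:
        raise ConfigError("LOPOCV undefined for fewer than 2 groups")
    rmses, imps = [], []
    for k, pid in enumerate(pids):
        held = groups == pid
        est = make_estimator(config, seed=seed + k)
        est.fit(matrix.X[~held], matrix.y[~held])
        pred = est.predict(matrix.X[held])
        rmses.append(float(np.sqrt(np.mean((pred - matrix.y[held]) ** 2))))
        imps.append(extract_importance(est, config))
    return float(np.mean(rmses)), np.mean(imps, axis=0)


def rfe_rank(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[list[str], list[tuple[int, float]], dict[int, list[str]]]:
    """Eliminate the least-important feature one at a time, down to one.

    Returns (elimination_order, cv_score_per_subset, subsets), where
    ``subsets[size]`` is the feature list evaluated at that size.  Equal
    importances drop the lexicographically last name.
    """
    config = config or ModelConfig()
    current = list(matrix.feature_names)
    if len(current) < 2:
        raise ConfigError("RFE needs at least 2 screened features")
    order: list[str] = []
    scores: list[tuple[int, float]] = []
    subsets: dict[int, list[str]] = {}
    while True:
        sub = matrix.restrict(current)
        rmse, imp = _logo_rmse(sub, config, seed)
        scores.append((len(current), rmse))
        subsets[len(current)] = list(current)
        if len(current) == 1:
            break
        worst = imp.min()
        ties = [n for n, v in zip(sub.feature_names, imp) if v == worst]
        drop = sorted(ties)[-1]  # lexicographically last among ties
        order.append(drop)
        current = [n for n in current if n != drop]
    return order, scores, subsets


def borfe_select(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    iterations: int = 100,
    alpha: float = 0.05,
    keep_tentative: bool = True,
    seed: int = 0,
) -> SelectionResult:
    """Boruta screening followed by LOPOCV-scored recursive elimination."""
    config = config or ModelConfig()
    boruta = boruta_screen(matrix, config, iterations=iterations,
                           alpha=alpha, seed=seed)
    survivors = set(boruta.confirmed)
    if keep_tentative:
        survivors |= boruta.tentative
    if not survivors:
        survivors = set(boruta.tentative)
    if not survivors:
        raise NoInformativeFeatures("no informative features")
    survivors_ordered = [n for n in matrix.feature_names if n in survivors]
    if len(survivors_ordered) == 1:
        selected = set(survivors_ordered)
        return SelectionResult(
            boruta=boruta, elimination_order=[],
            cv_score_per_subset=[], selected=selected,
            seeds={"master": seed, "boruta": seed, "rfe": seed + 1},
        )
    order, scores, subsets = rfe_rank(
        matrix.restrict(survivors_ordered), config, seed=seed + 1)
    # CV-optimal subset; ties prefer the smaller subset
    best_size, _ = min(scores, key=lambda sr: (sr[1], sr[0]))
    selected = set(subsets[best_size])
    log.info("BoRFE: %d confirmed, %d tentative -> selected %d feature(s)",
             len(boruta.confirmed), len(boruta.tentative), len(selected))
    return SelectionResult(
        boruta=boruta,
        elimination_order=order,
        cv_score_per_subset=scores,
        selected=selected,
        seeds={"master": seed, "boruta": seed, "rfe": seed + 1},
    )
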
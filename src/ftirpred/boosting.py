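"""Gradient boosting with random hyperparameter search and variable importance.

The learner is stagewise squared-error gradient boosting over depth-limited
regression trees (sklearn's ``GradientBoostingRegressor`` supplies the tree
machinery).  Hyperparameters are tuned by uniform random search over a fixed
grid — number of trees 100..3000 step 20, learning rate 0..1 step 0.1, max
depth 5..80 step 5, min samples per leaf 20..100 step 20, at most 100
candidate configurations — with inner 5-fold cross-validation on the
training set only; the winner maximizes inner R2 with MSE as tie-break.

Variable importance follows the classic boosting definition: for each
feature, the sum over all internal nodes splitting on that feature of the
squared improvement (weighted squared-error reduction) of the split,
accumulated over every tree and normalized to percentages summing to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import ConfigError, DataError

__all__ = [
    "GBMSearchSpace",
    "sample_search_space",
    "TunedGBMRegressor",
    "variable_importance",
    "significant_wavelengths",
    "shared_wavelength_counts",
]


@dataclass(frozen=True)
class GBMSearchSpace:
    """Hyperparameter grids for the random search."""

    ntree: tuple[int, int, int] = (100, 3000, 20)  # (lo, hi, step), inclusive
    learn_rate: tuple[float, float, float] = (0.0, 1.0, 0.1)
    max_depth: tuple[int, int, int] = (5, 80, 5)
    min_leaf: tuple[int, int, int] = (20, 100, 20)
    max_models: int = 100

    def grids(self) -> dict[str, np.ndarray]:
        lo, hi, st = self.ntree
        ntree = np.arange(lo, hi + 1, st)
        lo, hi, st = self.learn_rate
        lr = np.round(np.arange(lo, hi + st / 2, st), 10)
        lo, hi, st = self.max_depth
        depth = np.arange(lo, hi + 1, st)
        lo, hi, st = self.min_leaf
        leaf = np.arange(lo, hi + 1, st)
        return {"ntree": ntree, "learn_rate": lr, "max_depth": depth,
                "min_leaf": leaf}

    @property
    def grid_size(self) -> int:
        return int(np.prod([g.size for g in self.grids().values()]))


def sample_search_space(
    space: GBMSearchSpace, seed: int = 0
) -> list[dict[str, float]]:
    """Sample up to ``max_models`` unique configurations uniformly from the grid.

    When the grid is no larger than ``max_models`` the full product is
    enumerated instead.
    """
    grids = space.grids()
    names = list(grids)
    sizes = np.array([grids[k].size for k in names])
    total = int(sizes.prod())
    rng = np.random.default_rng(seed)
    if total <= space.max_models:
        combos = list(product(*(range(s) for s in sizes)))
    else:
        flat = rng.choice(total, size=space.max_models, replace=False)
        combos = [np.unravel_index(f, sizes) for f in flat]
    return [
        {k: grids[k][i].item() for k, i in zip(names, combo)}
        for combo in combos
    ]


def _inner_r2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    if y_obs.size < 2 or np.std(y_pred) == 0 or np.std(y_obs) == 0:
        return 0.0
    return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)


class _MeanModel:
    """Degenerate ensemble: zero shrinkage predicts the training mean."""

    def __init__(self, mean: float):
        self.mean_ = mean

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class TunedGBMRegressor(BaseEstimator, RegressorMixin):
    """Random-search-tuned gradient boosting regressor.

    ``fit`` runs the inner 5-fold tuning loop and refits the winning
    configuration on the full training data.  ``max_depth`` values beyond
    ceil(log2(n)) are capped (deep grids are vacuous at moderate n); the cap
    is recorded in ``manifest_``.  A sampled learning rate of exactly 0 is
    honored as a guarded mean-predicting model.
    """

    def __init__(
        self,
        space: GBMSearchSpace | None = None,
        n_inner_folds: int = 5,
        seed: int = 0,
    ):
        self.space = space
        self.n_inner_folds = n_inner_folds
        self.seed = seed

    def _make_model(self, cfg: dict, n: int) -> tuple[object, int]:
        depth_cap = int(np.ceil(np.log2(max(n, 2))))
        depth = int(min(cfg["max_depth"], depth_cap))
        if cfg["learn_rate"] == 0:
            return _MeanModel(0.0), depth
        return (
            GradientBoostingRegressor(
                n_estimators=int(cfg["ntree"]),
                learning_rate=float(cfg["learn_rate"]),
                max_depth=depth,
                min_samples_leaf=int(cfg["min_leaf"]),
                random_state=self.seed,
            ),
            depth,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if n < 10:
            raise DataError("need at least 10 training observations")
        if y.var() == 0:
            raise DataError("degenerate (constant) response")
        space = self.space if self.space is not None else GBMSearchSpace()
        configs = sample_search_space(space, seed=self.seed)
        kf = KFold(
            n_splits=self.n_inner_folds, shuffle=True, random_state=self.seed
        )
        splits = list(kf.split(X))
        log = []
        for ci, cfg in enumerate(configs):
            preds = np.empty(n)
            for tr, va in splits:
                model, _ = self._make_model(cfg, tr.size)
                if isinstance(model, _MeanModel):
                    model.mean_ = y[tr].mean()
                else:
                    model.fit(X[tr], y[tr])
                preds[va] = model.predict(X[va])
            r2 = _inner_r2(y, preds)
            mse = float(np.mean((y - preds) ** 2))
            log.append({**cfg, "inner_r2": r2, "inner_mse": mse})
        tuning = pd.DataFrame(log)
        best_idx = tuning.sort_values(
            ["inner_r2", "inner_mse"], ascending=[False, True]
        ).index[0]
        best = configs[best_idx]

        model, depth_used = self._make_model(best, n)
        if isinstance(model, _MeanModel):
            model.mean_ = y.mean()
        else:
            model.fit(X, y)
        self.model_ = model
        self.best_params_ = dict(best)
        self.tuning_log_ = tuning
        self.inner_r2_ = float(tuning.loc[best_idx, "inner_r2"])
        self.inner_mse_ = float(tuning.loc[best_idx, "inner_mse"])
        self.n_features_in_ = X.shape[1]
        self.manifest_ = {
            "best_params": self.best_params_,
            "max_depth_used": depth_used,
            "n_configs": len(configs),
            "seed": self.seed,
        }
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


def variable_importance(model: TunedGBMRegressor | GradientBoostingRegressor) -> np.ndarray:
    """Relative variable importance (%) from squared split improvements.

    For every internal node, the improvement is the weighted reduction in
    squared error achieved by the split; its square is credited to the
    splitting feature and summed over all trees, then normalized to sum to
    100 over features.
    """
    if isinstance(model, TunedGBMRegressor):
        ensemble = model.model_
        n_features = model.n_features_in_
    else:
        ensemble = model
        n_features = ensemble.n_features_in_
    if isinstance(ensemble, _MeanModel):
        raise DataError("mean-only ensemble has no splits: importance undefined")
    raw = np.zeros(n_features)
    for stage in ensemble.estimators_.ravel():
        t = stage.tree_
        left, right = t.children_left, t.children_right
        w = t.weighted_n_node_samples
        imp = t.impurity
        for node in range(t.node_count):
            if left[node] == -1:
                continue
            gain = (
                w[node] * imp[node]
                - w[left[node]] * imp[left[node]]
                - w[right[node]] * imp[right[node]]
            )
            raw[t.feature[node]] += gain * gain
    total = raw.sum()
    if total == 0:
        raise DataError("ensemble contains no effective splits")
    return 100.0 * raw / total


def significant_wavelengths(
    vi: np.ndarray, threshold: float = 0.8
) -> np.ndarray:
    """Indices of features whose relative importance exceeds ``threshold`` %."""
    vi = np.asarray(vi, dtype=float)
    return np.flatnonzero(vi > threshold)


def shared_wavelength_counts(
    selected: dict[str, np.ndarray],
) -> pd.Series:
    """Per-feature count of traits selecting it (overlap analysis)."""
    from collections import Counter

    counts: Counter = Counter()
    for feats in selected.values():
        counts.update(int(f) for f in np.asarray(feats))
    return pd.Series(dict(counts), dtype=int).sort_index()
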
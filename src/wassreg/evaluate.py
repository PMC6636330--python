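"""Evaluation protocol: top-k marker selection, ridge prediction on the
selected features, and RMSE under nested five-fold cross-validation.

The protocol mirrors how marker-selection regressions are compared in
neuroimaging association studies: a selector (the transport-based model or a
baseline) is fitted on training data only, its top-k features by weight-row
norm are kept, a ridge predictor is refitted on those features, and the test
root-mean-square error is reported. Hyper-parameters are chosen on inner
folds of the training split, never on test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .baselines import l21_fs_fit, ridge_fit
from .errors import ConfigError, DimensionError, ValidationError
from .model import JWMRParams, WassersteinMatrixRegression
from .selection import select_top_k

__all__ = ["CVResult", "rmse", "rmse_overall", "default_grid",
           "fit_selector", "select_then_predict", "nested_cv"]

SELECTORS = ("jwmr", "ridge", "l21")


def rmse(pred, truth) -> np.ndarray:
    """Per-column root-mean-square error between two matrices."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise DimensionError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.shape[0] < 1:
        raise DimensionError("need at least one row")
    return np.sqrt(np.mean((pred - truth) ** 2, axis=0))


def rmse_overall(pred, truth) -> float:
    """Mean of the per-column RMSEs."""
    return float(np.mean(rmse(pred, truth)))


def default_grid() -> np.ndarray:
    """The standard hyper-parameter grid 1e-4, 1e-3, ..., 1e4 (nine values)."""
    return np.logspace(-4, 4, 9)


def fit_selector(selector: str, A, Y, lam: float,
                 jwmr_params: JWMRParams | None = None):
    """Fit the named selector and return its feature ranking.

    ``lam`` is the selector's single tunable; for the transport-based model
    the entropic weight gamma and marginal weight mu stay at their defaults
    (or those of ``jwmr_params``) and only lam is swept.
    """
    if selector == "ridge":
        return ridge_fit(A, Y, lam=max(lam, 1e-12)).rank_features()
    if selector == "l21":
        return l21_fs_fit(A, Y, lam=lam).rank_features()
    if selector == "jwmr":
        base = jwmr_params if jwmr_params is not None else JWMRParams()
        model = WassersteinMatrixRegression(A, Y)
        return model.fit(params=base, lam=lam).rank_features()
    raise ConfigError(f"unknown selector {selector!r}; choose from {SELECTORS}")


def select_then_predict(A_train, Y_train, A_test, selector: str, k: int,
                        lam_selector: float, lam_ridge: float,
                        jwmr_params: JWMRParams | None = None) -> np.ndarray:
    """Top-k selection on training data, ridge prediction on the kept features.

    Returns test-set score predictions in the original score units (the
    post-selection predictor is fitted on the unscaled training scores, so no
    inverse transform is needed). The predictor carries an unpenalized
    intercept so the score means are not shrunk away.
    """
    A_train = np.asarray(A_train, dtype=float)
    A_test = np.asarray(A_test, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if not 1 <= k <= A_train.shape[0]:
        raise ValidationError(f"k must be in [1, {A_train.shape[0]}]")
    ranking = fit_selector(selector, A_train, Y_train, lam_selector, jwmr_params)
    keep = select_top_k(ranking, k)
    predictor = ridge_fit(A_train[keep], Y_train, lam=lam_ridge, fit_intercept=True)
    return predictor.predict(A_test[keep])


@dataclass(frozen=True)
class CVResult:
    """Nested cross-validation outcome for one selector and one k."""

    selector: str
    k: int
    seed: int
    fold_rmse: np.ndarray            # n_outer x n_tasks
    chosen: tuple                    # per outer fold: (lam_selector, lam_ridge)
    score_names: tuple
    grid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def mean_rmse(self) -> float:
        return float(self.fold_rmse.mean())

    @property
    def task_rmse(self) -> np.ndarray:
        return self.fold_rmse.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (fold, task) plus a mean summary row."""
        rows = []
        for f in range(self.fold_rmse.shape[0]):
            lam_sel, lam_rid = self.chosen[f]
            for t, name in enumerate(self.score_names):
                rows.append({"method": self.selector, "task": name, "fold": f,
                             "k": self.k, "rmse": self.fold_rmse[f, t],
                             "lam_selector": lam_sel, "lam_ridge": lam_rid})
        rows.append({"method": self.selector, "task": "ALL", "fold": -1,
                     "k": self.k, "rmse": self.mean_rmse,
                     "lam_selector": np.nan, "lam_ridge": np.nan})
        return pd.DataFrame(rows)


def nested_cv(A, Y, selector: str, k: int, grid=None, seed: int = 0,
              n_outer: int = 5, n_inner: int = 5,
              jwmr_params: JWMRParams | None = None,
              score_names=None) -> CVResult:
    """Nested k-fold protocol: inner folds pick hyper-parameters, outer folds score.

    The outer loop splits samples into ``n_outer`` folds (seeded shuffle). On
    each outer-training set an inner ``n_inner``-fold loop evaluates every
    (selector lam, predictor ridge lam) pair from ``grid`` and keeps the pair
    with the smallest mean inner RMSE; the selector is then refitted on the
    full outer-training set with the chosen pair and scored on the held-out
    outer fold. Test rows are never visible to any fitting or grid decision.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    l = A.shape[1]
    if Y.shape[0] != l:
        raise DimensionError("A and Y disagree on the number of samples")
    if l < 2 * n_outer:
        raise ValidationError(f"need at least {2 * n_outer} samples for nested CV")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("hyper-parameter grid is empty")
    if selector not in SELECTORS:
        raise ConfigError(f"unknown selector {selector!r}")
    names = tuple(score_names) if score_names is not None else tuple(
        f"score_{t}" for t in range(Y.shape[1]))

    outer = KFold(n_splits=n_outer, shuffle=True, random_state=seed)
    fold_rmse = []
    chosen = []
    for tr_idx, te_idx in outer.split(np.arange(l)):
        A_tr, Y_tr = A[:, tr_idx], Y[tr_idx]
        inner = KFold(n_splits=n_inner, shuffle=True, random_state=seed + 1)
        splits = list(inner.split(np.arange(tr_idx.size)))
        # selector fits depend only on lam_sel: cache rankings per inner fold
        best = (np.inf, grid[0], grid[0])
        for lam_sel in grid:
            rankings = []
            for itr, _ in splits:
                rankings.append(fit_selector(
                    selector, A_tr[:, itr], Y_tr[itr], lam_sel, jwmr_params))
            for lam_rid in grid:
                errs = []
                for (itr, ite), ranking in zip(splits, rankings):
                    keep = select_top_k(ranking, min(k, A.shape[0]))
                    pred = ridge_fit(A_tr[:, itr][keep], Y_tr[itr], lam=lam_rid,
                                     fit_intercept=True).predict(A_tr[:, ite][keep])
                    errs.append(rmse_overall(pred, Y_tr[ite]))
                score = float(np.mean(errs))
                if score < best[0] - 1e-15:
                    best = (score, float(lam_sel), float(lam_rid))
        _, lam_sel, lam_rid = best
        pred = select_then_predict(A_tr, Y_tr, A[:, te_idx], selector,
                                   min(k, A.shape[0]), lam_sel, lam_rid, jwmr_params)
        fold_rmse.append(rmse(pred, Y[te_idx]))
        chosen.append((lam_sel, lam_rid))
    return CVResult(selector=selector, k=k, seed=int(seed),
                    fold_rmse=np.asarray(fold_rmse), chosen=tuple(chosen),
                    score_names=names, grid=grid)
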
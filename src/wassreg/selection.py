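"""Feature ranking and top-k marker selection from a fitted weight matrix.

A feature's importance is the l2 norm of its weight row: a row that carries
mass for any score task keeps its feature in the model, a row driven to zero
mass drops it. Ranking is descending with ties broken by the original index,
so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError

__all__ = ["FeatureRanking", "l21_norm", "rank_features", "select_top_k"]


def l21_norm(M) -> float:
    """Sum of row-wise l2 norms, the norm that induces whole-row sparsity."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise DimensionError("l2,1 norm needs a nonempty matrix")
    return float(np.linalg.norm(M, axis=1).sum())


@dataclass(frozen=True)
class FeatureRanking:
    """Permutation of feature indices, most important first.

    ``order[r]`` is the index of the rank-r feature; ``scores[r]`` is its row
    l2 norm (non-increasing along ``order``); ``names`` follows ``order``.
    """

    order: np.ndarray
    scores: np.ndarray
    names: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": list(self.names), "score": self.scores})


def rank_features(Z, names) -> FeatureRanking:
    """Rank features by descending l2 norm of the rows of ``Z``.

    Ties are broken by ascending original index (stable sort on the negated
    norms), so equal-norm features keep their input order.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise DimensionError("weight matrix must be 2-D")
    names = list(names)
    if len(names) != Z.shape[0]:
        raise DimensionError(
            f"{len(names)} names for {Z.shape[0]} features")
    norms = np.linalg.norm(Z, axis=1)
    order = np.argsort(-norms, kind="stable")
    return FeatureRanking(
        order=order,
        scores=norms[order],
        names=tuple(names[j] for j in order),
    )


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """First ``k`` feature indices of the ranking."""
    m = ranking.order.size
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    return ranking.order[:k].copy()
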
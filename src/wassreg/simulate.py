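"""Synthetic instances with known sparse nonnegative ground truth.

The generator emulates the structure of regional imaging-marker tables
(nonnegative gray-matter density / volumetric values, features x subjects)
paired with a handful of cognitive score columns: scores are linear in the
features through a ground-truth weight matrix with exactly ``s`` active
feature rows, plus Gaussian noise, clipped nonnegative and min-max scaled per
column onto [0.01, 1]. Knowing the true support lets every stage — fitting,
ranking, top-k selection, cross-validated prediction — be tested end to end
without any restricted-access data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .selection import FeatureRanking, select_top_k

__all__ = ["SyntheticInstance", "generate", "support_recovery"]


@dataclass(frozen=True)
class SyntheticInstance:
    """One simulated dataset with its generating truth."""

    A: np.ndarray          # m x l nonnegative features
    Y: np.ndarray          # l x n scores, scaled to [0.01, 1] per column
    Z_true: np.ndarray     # m x n, exactly s nonzero rows, active rows unit l2
    support: np.ndarray    # sorted indices of the s active feature rows
    noise_sd: float
    seed: int

    @property
    def shape(self) -> tuple:
        m, l = self.A.shape
        return m, l, self.Y.shape[1]


def generate(m: int, l: int, n: int, s: int, noise_sd: float, seed: int) -> SyntheticInstance:
    """Draw one reproducible instance.

    Features are |N(0,1)| (nonnegative, like density/volume markers; the
    absolute scale is irrelevant after score scaling). The ``s`` active rows of
    the true weight matrix are |N(0,1)| normalized to unit l2 norm. Scores are
    ``A'Z_true`` plus N(0, noise_sd^2) noise, clipped at zero, then min-max
    scaled per column onto [0.01, 1]; ``noise_sd`` is interpreted on the
    pre-scaling score scale.
    """
    if not 1 <= s <= m:
        raise ValidationError(f"need 1 <= s <= m, got s={s}, m={m}")
    if l < 2 or n < 2:
        raise ValidationError("need at least 2 samples and 2 score tasks")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    A = np.abs(rng.standard_normal((m, l)))
    support = np.sort(rng.choice(m, size=s, replace=False))
    Z = np.zeros((m, n))
    rows = np.abs(rng.standard_normal((s, n)))
    rows /= np.linalg.norm(rows, axis=1, keepdims=True)
    Z[support] = rows
    Y = A.T @ Z + noise_sd * rng.standard_normal((l, n))
    Y = np.maximum(Y, 0.0)
    lo, hi = Y.min(axis=0), Y.max(axis=0)
    rngc = np.where(hi > lo, hi - lo, 1.0)
    Y = 0.01 + 0.99 * (Y - lo) / rngc
    return SyntheticInstance(A=A, Y=Y, Z_true=Z, support=support,
                             noise_sd=float(noise_sd), seed=int(seed))


def support_recovery(ranking: FeatureRanking, Z_true, k: int) -> float:
    """Fraction of the true active rows found among the top-k ranked features.

    Normalized by ``min(k, s)`` so a perfect ranking scores 1.0 whether k is
    below or above the true support size.
    """
    Z_true = np.asarray(Z_true, dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    true_support = set(np.flatnonzero(np.linalg.norm(Z_true, axis=1) > 0).tolist())
    if not true_support:
        raise ValidationError("ground truth has empty support")
    top = set(select_top_k(ranking, min(k, ranking.order.size)).tolist())
    return len(top & true_support) / min(k, len(true_support))
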
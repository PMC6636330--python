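"""Wasserstein-distance matrix regression.

The model predicts a multi-task score matrix ``Y`` (samples x score tasks)
from a nonnegative feature matrix ``A`` (features x samples) through a
nonnegative weight matrix ``Z`` (features x tasks). Both the empirical loss
and the row-sparsity regularizer are entropy-smoothed, KL-relaxed transport
costs over score space:

    min_{Z >= 0}  sum_i f_{(A'Z)^i, Y^i}(P^(i))  +  lam * sum_j f_{Z^j, t}(Phat^(j))

with ``f_{a,b}(P) = gamma KL(P|K) + mu KL(P1|a) + mu KL(P'1|b)`` the relaxed
transport objective (see :mod:`wassreg.ot`). The loss compares each sample's
predicted score row with its observed row as discrete measures over the
``n`` tasks; the regularizer transports each feature's weight row toward a
(near-)zero target measure ``t``, so features whose rows can be emptied
without hurting the fit are driven to zero mass — whole-feature selection
driven by the transport geometry rather than by a matrix norm.

Optimization is block coordinate descent: with ``Z`` fixed, every transport
plan is an independent relaxed-Sinkhorn problem (solved batched); with plans
fixed, ``Z`` solves a smooth convex KL-fitting problem by monotone accelerated
projected gradient. Each block is minimized (plans exactly, ``Z`` to descent),
so the joint objective is non-increasing across sweeps.

Because the exact zero target makes ``KL(.|0)`` infinite for any transported
mass, the regularizer target is either a small uniform measure ``eps_target*1``
(``reg_mode="epsilon"``, the default, which keeps the plan updates uniform) or
the analytic ``eps_target -> 0`` limit (``reg_mode="limit"``), in which the
per-row penalty collapses to ``gamma * sum(K) + mu * ||Z^j||_1`` with a null
plan — an entropic constant plus a plain l1 row penalty.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ot
from .errors import ConfigError, DimensionError, ValidationError
from .selection import FeatureRanking, rank_features

__all__ = [
    "JWMRParams",
    "WassersteinMatrixRegression",
    "JWMRResults",
    "histogram_op",
    "objective_value",
    "update_plans",
    "update_weights",
    "weight_gradient",
]


def histogram_op(x, mode: str = "identity"):
    """Map a raw real vector to a nonnegative mass vector.

    "identity" validates nonnegativity and passes the vector through (the
    relaxed transport formulation consumes raw feature/score rows directly, no
    binning); "clip" zeroes negative entries; "shift" subtracts the minimum
    when it is negative. No normalization to unit mass is applied — unbalanced
    transport absorbs mass differences.

    Returns ``(mass_vector, n_modified)`` where ``n_modified`` counts entries
    changed by clip/shift (always 0 for identity).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("histogram operator requires finite entries")
    if mode == "identity":
        if np.any(x < 0):
            bad = int(np.flatnonzero((x < 0).reshape(-1))[0])
            raise ValidationError(
                f"identity histogram mode requires nonnegative input; "
                f"first negative entry at flat index {bad}"
            )
        return x.copy(), 0
    if mode == "clip":
        neg = x < 0
        return np.where(neg, 0.0, x), int(neg.sum())
    if mode == "shift":
        mn = x.min()
        if mn < 0:
            return x - mn, int(x.size)
        return x.copy(), 0
    raise ConfigError(f"unknown histogram mode {mode!r}")


@dataclass(frozen=True)
class JWMRParams:
    """Hyper-parameters of the Wasserstein matrix regression.

    gamma : entropic smoothing weight of every transport term (> 0).
    mu : weight of the KL marginal penalties in the relaxed transport (> 0).
    lam : regularization weight trading fit against row sparsity (>= 0).
    eps_target : level of the uniform near-zero regularizer target measure.
    eps_z : strict-positivity floor on the weights (the KL penalty needs
        ``Z > 0``); fitted entries at or near the floor are dead features.
    reg_mode : "epsilon" (finite target, plans computed) or "limit"
        (analytic zero-target limit: l1 row penalty, null plans).
    outer_tol / outer_max : relative-change stop / cap for coordinate sweeps.
    inner_tol / inner_max : stop / cap for the accelerated Z updates.
    sink_tol / sink_max : stop / cap for the Sinkhorn scaling iterations.
    seed : recorded for provenance; the fit itself is deterministic.
    """

    gamma: float = 0.05
    mu: float = 1.0
    lam: float = 1.0
    eps_target: float = 1e-6
    eps_z: float = 1e-8
    reg_mode: str = "epsilon"
    outer_tol: float = 1e-6
    outer_max: int = 50
    inner_tol: float = 1e-8
    inner_max: int = 500
    sink_tol: float = 1e-9
    sink_max: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0 or self.mu <= 0:
            raise ConfigError("gamma and mu must be positive")
        if self.lam < 0:
            raise ConfigError("lam must be nonnegative")
        if self.eps_target <= 0 or self.eps_z <= 0:
            raise ConfigError("eps_target and eps_z must be positive")
        if self.reg_mode not in ("epsilon", "limit"):
            raise ConfigError(f"reg_mode must be 'epsilon' or 'limit', got {self.reg_mode!r}")


class _ScoreScaler:
    """Per-column min-max map of the score matrix onto [0.01, 1].

    The KL terms need strictly positive measures; raw cognitive scores can be
    zero or arbitrarily scaled, so each column is affinely mapped onto
    [0.01, 1] before fitting and predictions are mapped back. A constant
    column maps to its midpoint and inverts back to the constant.
    """

    lo, hi = 0.01, 1.0

    def __init__(self, Y: np.ndarray):
        self.mins = Y.min(axis=0)
        self.maxs = Y.max(axis=0)

    def transform(self, Y: np.ndarray) -> np.ndarray:
        rng = self.maxs - self.mins
        out = np.empty_like(Y, dtype=float)
        const = rng <= 0
        safe = np.where(const, 1.0, rng)
        out[:] = self.lo + (self.hi - self.lo) * (Y - self.mins) / safe
        out[:, const] = 0.5 * (self.lo + self.hi)
        return out

    def inverse(self, Ys: np.ndarray) -> np.ndarray:
        rng = self.maxs - self.mins
        out = self.mins + (Ys - self.lo) * rng / (self.hi - self.lo)
        const = rng <= 0
        out[:, const] = self.mins[const]
        return out

    def to_dict(self) -> dict:
        return {"kind": "minmax", "mins": self.mins.tolist(), "maxs": self.maxs.tolist()}


class _IdentityScaler:
    """No-op scaler used when the caller opts out of score scaling."""

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return np.asarray(Y, dtype=float)

    def inverse(self, Ys: np.ndarray) -> np.ndarray:
        return np.asarray(Ys, dtype=float)

    def to_dict(self) -> dict:
        return {"kind": "identity"}


# ---------------------------------------------------------------------------
# objective, plan updates, weight updates (the three blocks of the algorithm)
# ---------------------------------------------------------------------------

def objective_value(Z, loss_plans, reg_plans, A, Ys, C_loss, C_reg, p: JWMRParams) -> float:
    """Joint objective at the given weights and transport plans.

    ``loss_plans`` is an ``l x n x n`` array (one plan per sample row),
    ``reg_plans`` an ``m x n x n`` array (one per feature row; ignored and may
    be None in reg_mode="limit"). ``Ys`` is the scaled ``l x n`` score matrix.
    """
    Z = np.asarray(Z, dtype=float)
    m, n = Z.shape
    l = Ys.shape[0]
    if A.shape != (m, l) or Ys.shape != (l, n):
        raise DimensionError("A, Y, Z dimensions do not conform")
    K_loss = np.exp(-C_loss / p.gamma)
    K_reg = np.exp(-C_reg / p.gamma)
    pred = A.T @ Z  # l x n
    total = 0.0
    for i in range(l):
        total += ot.relaxed_objective(loss_plans[i], K_loss, pred[i], Ys[i], p.gamma, p.mu)
    if p.lam > 0:
        if p.reg_mode == "limit":
            total += p.lam * (p.gamma * K_reg.sum() * m + p.mu * Z.sum())
        else:
            t = np.full(n, p.eps_target)
            for j in range(m):
                total += p.lam * ot.relaxed_objective(reg_plans[j], K_reg, Z[j], t, p.gamma, p.mu)
    if not np.isfinite(total):
        raise FloatingPointError("objective is non-finite")
    return float(total)


def update_plans(Z, A, Ys, C_loss, C_reg, p: JWMRParams):
    """Exact block update of all transport plans for fixed weights.

    Every plan solves an independent relaxed-Sinkhorn problem; the loss plans
    couple each predicted score row ``(A'Z)^i`` with the observed ``Y^i``, the
    regularizer plans couple each weight row ``Z^j`` with the target measure.
    Returns ``(loss_plans, reg_plans, info)`` as stacked arrays (``reg_plans``
    is all-zero in reg_mode="limit", matching the analytic limit).
    """
    Z = np.asarray(Z, dtype=float)
    m, n = Z.shape
    pred = A.T @ Z  # l x n, strictly positive given A has positive column sums
    U, V, K, conv_l, _ = ot.sinkhorn_relaxed_batch(
        pred.T, Ys.T, C_loss, p.gamma, p.mu, tol=p.sink_tol, max_iter=p.sink_max)
    loss_plans = ot.batch_plans(U, V, K)
    loss_row = ot.batch_row_marginals(U, V, K).T  # l x n
    if p.reg_mode == "limit" or p.lam == 0:
        reg_plans = np.zeros((m, n, n))
        reg_row = np.zeros((m, n))
        conv_r = True
    else:
        T = np.full((n, m), p.eps_target)
        Ur, Vr, Kr, conv_r, _ = ot.sinkhorn_relaxed_batch(
            Z.T, T, C_reg, p.gamma, p.mu, tol=p.sink_tol, max_iter=p.sink_max)
        reg_plans = ot.batch_plans(Ur, Vr, Kr)
        reg_row = ot.batch_row_marginals(Ur, Vr, Kr).T  # m x n
    info = {"loss_row": loss_row, "reg_row": reg_row,
            "converged": bool(conv_l and conv_r)}
    return loss_plans, reg_plans, info


def weight_gradient(Z, loss_row, reg_row, A, p: JWMRParams) -> np.ndarray:
    """Gradient of the weight-block objective ``g`` at ``Z``.

    ``g(Z) = mu * sum_i KL(c^(i) | (A'Z)^i) + lam*mu * sum_j KL(d^(j) | Z^j)``
    where ``c^(i)``/``d^(j)`` are the fixed row marginals of the loss and
    regularizer plans (``loss_row``: l x n, ``reg_row``: m x n). With
    ``KL(c|y)`` differentiated in its second argument the entrywise gradient is

        mu * sum_i A[j,i] * (1 - c^(i)_k / (A'Z)[i,k])  +  lam*mu * (1 - d^(j)_k / Z[j,k])

    and in reg_mode="limit" the second term is the l1 gradient ``lam*mu``.
    """
    Z = np.asarray(Z, dtype=float)
    pred = A.T @ Z
    G = p.mu * (A @ (1.0 - loss_row / pred))
    if p.lam > 0:
        if p.reg_mode == "limit":
            G = G + p.lam * p.mu
        else:
            G = G + p.lam * p.mu * (1.0 - reg_row / Z)
    return G


def _g_value(Z, loss_row, reg_row, A, p: JWMRParams) -> float:
    pred = A.T @ Z
    val = p.mu * ot._gkl_cols(loss_row.T, pred.T).sum()
    if p.lam > 0:
        if p.reg_mode == "limit":
            val += p.lam * p.mu * Z.sum()
        else:
            val += p.lam * p.mu * ot._gkl_cols(reg_row.T, Z.T).sum()
    return float(val)


def update_weights(Z0, loss_row, reg_row, A, p: JWMRParams):
    """Monotone accelerated projected-gradient update of the weight block.

    Minimizes the convex ``g`` of :func:`weight_gradient` over ``Z >= eps_z``
    using FISTA with backtracking (halving the step until the quadratic upper
    bound holds) and the monotone safeguard that keeps the running iterate's
    objective non-increasing. Returns ``(Z, g(Z), warn)``; ``warn`` is True if
    backtracking underflowed, in which case the best iterate found is returned.
    """
    x = np.maximum(np.asarray(Z0, dtype=float), p.eps_z)
    gx = _g_value(x, loss_row, reg_row, A, p)
    y = x.copy()
    t = 1.0
    L = 1.0
    warn = False
    for _ in range(p.inner_max):
        gy = _g_value(y, loss_row, reg_row, A, p)
        grad = weight_gradient(y, loss_row, reg_row, A, p)
        # backtracking line search on the projected step from y
        while True:
            z = np.maximum(y - grad / L, p.eps_z)
            gz = _g_value(z, loss_row, reg_row, A, p)
            dz = z - y
            bound = gy + float(np.sum(grad * dz)) + 0.5 * L * float(np.sum(dz * dz))
            if gz <= bound + 1e-12 * max(1.0, abs(bound)):
                break
            L *= 2.0
            if L > 1e18:
                warn = True
                break
        if warn:
            break
        if gz > gx:
            # monotone safeguard: reject the step and restart the momentum
            y = x.copy()
            t = 1.0
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = np.maximum(
            z + ((t - 1.0) / t_new) * (z - x),
            p.eps_z,
        )
        rel_drop = (gx - gz) / max(1.0, abs(gx))
        x, gx, t = z, gz, t_new
        L = max(L * 0.5, 1e-12)
        if rel_drop < p.inner_tol:
            break
    return x, gx, warn


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class WassersteinMatrixRegression:
    """Multi-task regression with transport-based loss and row regularizer.

    Parameters
    ----------
    A : array-like, shape (m, l)
        Feature matrix, features x samples (e.g. imaging markers per subject).
        Must be nonnegative under the default histogram mode.
    Y : array-like, shape (l, n)
        Score matrix, samples x score tasks. Columns are min-max scaled onto
        [0.01, 1] internally; the scaler is stored and inverted on predict.
    feature_names, score_names : optional sequences of labels.
    cost_mode : "index" or "data" — how the score-space ground cost is built
        (see :func:`wassreg.ot.build_ground_cost`).
    histogram_mode : "identity", "clip" or "shift" — how raw rows are mapped
        to mass vectors before fitting.
    scale_scores : set False to fit on the raw (already strictly positive)
        scores without the min-max map; predictions then come back unscaled.
    """

    def __init__(self, A, Y, feature_names=None, score_names=None,
                 cost_mode: str = "index", histogram_mode: str = "identity",
                 scale_scores: bool = True):
        A = np.asarray(A, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if A.ndim != 2 or Y.ndim != 2:
            raise DimensionError("A and Y must be matrices")
        if A.shape[1] != Y.shape[0]:
            raise DimensionError(
                f"A has {A.shape[1]} samples (columns) but Y has {Y.shape[0]} rows")
        if Y.shape[0] < 2 or Y.shape[1] < 2:
            raise ValidationError("need at least 2 samples and 2 score tasks")
        A_rows = []
        self.n_clipped_ = 0
        for j in range(A.shape[0]):
            try:
                row, nmod = histogram_op(A[j], histogram_mode)
            except ValidationError as exc:
                raise ValidationError(f"feature row {j}: {exc}") from None
            A_rows.append(row)
            self.n_clipped_ += nmod
        self.A = np.vstack(A_rows)
        Y_rows = []
        for i in range(Y.shape[0]):
            try:
                row, nmod = histogram_op(Y[i], histogram_mode)
            except ValidationError as exc:
                raise ValidationError(f"score row {i}: {exc}") from None
            Y_rows.append(row)
            self.n_clipped_ += nmod
        self.Y = np.vstack(Y_rows)
        m, l = self.A.shape
        n = self.Y.shape[1]
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"feature_{j:04d}" for j in range(m)]
        self.score_names = list(score_names) if score_names is not None \
            else [f"score_{k}" for k in range(n)]
        if len(self.feature_names) != m:
            raise DimensionError("feature_names length must equal the number of features")
        if len(self.score_names) != n:
            raise DimensionError("score_names length must equal the number of score tasks")
        self.cost_mode = cost_mode
        self.histogram_mode = histogram_mode
        self.scale_scores = scale_scores
        if scale_scores:
            self.scaler_ = _ScoreScaler(self.Y)
            self.Ys_ = self.scaler_.transform(self.Y)
        else:
            if np.any(self.Y <= 0):
                raise ValidationError(
                    "scale_scores=False requires strictly positive scores")
            self.scaler_ = _IdentityScaler()
            self.Ys_ = self.Y.copy()
        self.C_ = ot.build_ground_cost(n, cost_mode, Y=self.Ys_ if cost_mode == "data" else None)

    @classmethod
    def from_dataframes(cls, features: pd.DataFrame, scores: pd.DataFrame, **kwargs):
        """Build from a features x samples frame and a samples x scores frame."""
        common = [s for s in features.columns if s in set(scores.index)]
        if len(common) < 2:
            raise ValidationError("feature columns and score rows share fewer than 2 samples")
        return cls(
            features[common].to_numpy(dtype=float),
            scores.loc[common].to_numpy(dtype=float),
            feature_names=list(features.index),
            score_names=list(scores.columns),
            **kwargs,
        )

    def fit(self, params: JWMRParams | None = None, **overrides) -> "JWMRResults":
        """Run block coordinate descent and return the fitted results.

        The weights are warm-started from the ridge solution (clipped at the
        positivity floor) and plans from one exact plan update; thereafter each
        sweep updates the weight block (monotone accelerated gradient) and all
        transport plans (batched relaxed Sinkhorn) until the relative objective
        change drops below ``outer_tol``. The recorded objective trace is
        non-increasing up to solver tolerance — the convergence guarantee of
        block descent on this jointly convex-in-blocks objective.
        """
        if params is None:
            params = JWMRParams(**overrides)
        elif overrides:
            params = dataclasses.replace(params, **overrides)
        p = params
        A, Ys, C = self.A, self.Ys_, self.C_
        m, l = A.shape
        n = Ys.shape[1]
        if np.any(A.sum(axis=0) <= 0):
            raise ValidationError("every sample needs positive total feature mass")

        from .baselines import ridge_fit  # deferred: baselines imports selection
        Z = np.maximum(ridge_fit(A, Ys, lam=1.0).Z, p.eps_z)
        loss_plans, reg_plans, info = update_plans(Z, A, Ys, C, C, p)
        trace = [objective_value(Z, loss_plans, reg_plans, A, Ys, C, C, p)]
        converged = False
        warn_inner = False
        for _ in range(p.outer_max):
            Z, _, warn = update_weights(Z, info["loss_row"], info["reg_row"], A, p)
            warn_inner = warn_inner or warn
            loss_plans, reg_plans, info = update_plans(Z, A, Ys, C, C, p)
            J = objective_value(Z, loss_plans, reg_plans, A, Ys, C, C, p)
            trace.append(J)
            prev = trace[-2]
            if abs(prev - J) <= p.outer_tol * max(1.0, abs(prev)):
                converged = True
                break
        return JWMRResults(
            model=self,
            params=p,
            Z=Z,
            loss_plans=loss_plans,
            reg_plans=reg_plans,
            objective_trace=np.asarray(trace),
            converged=converged,
            inner_warning=warn_inner,
        )


@dataclass
class JWMRResults:
    """Fitted state: weights, transport plans, objective trace, diagnostics."""

    model: WassersteinMatrixRegression
    params: JWMRParams
    Z: np.ndarray
    loss_plans: np.ndarray
    reg_plans: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    inner_warning: bool = False

    @property
    def Z_selected(self) -> np.ndarray:
        """Weights with numerically dead entries (<= 10 * eps_z) floored to 0."""
        return np.where(self.Z <= 10.0 * self.params.eps_z, 0.0, self.Z)

    def predict(self, A_new) -> np.ndarray:
        """Predict scores for new samples, mapped back to original units."""
        A_new = np.asarray(A_new, dtype=float)
        if A_new.shape[0] != self.Z.shape[0]:
            raise DimensionError("A_new must have one row per fitted feature")
        return self.model.scaler_.inverse(A_new.T @ self.Z)

    def rank_features(self) -> FeatureRanking:
        """Rank features by descending l2 norm of their weight rows."""
        return rank_features(self.Z_selected, self.model.feature_names)

    def transport_plan(self, which: str, i: int) -> ot.TransportPlan:
        """The fitted coupling for sample i ("loss") or feature i ("reg")."""
        plans = self.loss_plans if which == "loss" else self.reg_plans
        return ot.TransportPlan(plans[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z_selected, index=self.model.feature_names,
                            columns=self.model.score_names)

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: dimensions, hyper-parameters, objective, top features."""
        m, l = self.model.A.shape
        n = self.model.Ys_.shape[1]
        p = self.params
        ranking = self.rank_features()
        lines = [
            "Wasserstein Matrix Regression Results",
            "=" * 53,
            f"features (m): {m:>6}    samples (l): {l:>6}    tasks (n): {n:>4}",
            f"gamma: {p.gamma:g}   mu: {p.mu:g}   lambda: {p.lam:g}   reg_mode: {p.reg_mode}",
            f"outer sweeps: {len(self.objective_trace) - 1}   converged: {self.converged}",
            f"objective: {self.objective_trace[0]:.6g} -> {self.objective_trace[-1]:.6g}",
            f"active features (row norm > 0): "
            f"{int(np.sum(np.linalg.norm(self.Z_selected, axis=1) > 0))}",
            "-" * 53,
            f"{'rank':>4}  {'feature':<24} {'row l2 norm':>12}",
        ]
        for r, j in enumerate(ranking.order[:top]):
            lines.append(
                f"{r + 1:>4}  {self.model.feature_names[j]:<24} {ranking.scores[r]:>12.6f}")
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Plot the objective trace across coordinate-descent sweeps."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.objective_trace)), self.objective_trace, marker="o")
        ax.set_xlabel("outer sweep")
        ax.set_ylabel("objective J")
        ax.set_title("Block coordinate descent objective")
        return ax
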
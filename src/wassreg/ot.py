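"""Discrete optimal-transport primitives.

This module holds the numerical core used by the regression model: the
generalized (unnormalized) Kullback-Leibler divergence, an exact linear-program
transport oracle, balanced entropic Sinkhorn scaling, and the KL-relaxed
(unbalanced) Sinkhorn solver that tolerates mass mismatch between the two
measures — including an all-zero target, which is what the row-sparsity
regularizer of the regression model exploits.

Conventions
-----------
* A discrete measure is a nonnegative 1-D array; it need not sum to one.
* Ground costs are symmetric, zero-diagonal and rescaled so the largest entry
  is 1 (``build_ground_cost`` enforces this), which makes the entropic weight
  ``gamma`` data-independent.
* ``0 * log 0 = 0`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.special import logsumexp

from .errors import BalanceError, ConfigError, DimensionError, SolverError

__all__ = [
    "TransportPlan",
    "generalized_kl",
    "build_ground_cost",
    "exact_ot",
    "sinkhorn_balanced",
    "sinkhorn_relaxed",
    "relaxed_objective",
]

#: floor applied to scaling vectors / denominators to avoid division blow-ups
_SCALE_FLOOR = 1e-300
#: below this entropic weight the solvers switch to log-domain arithmetic
_LOG_DOMAIN_GAMMA = 1e-2


def _as_mass_vector(x, name: str = "measure") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DimensionError(f"{name} must be 1-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(x < 0):
        raise ValueError(f"{name} contains negative entries")
    return x


@dataclass(frozen=True)
class TransportPlan:
    """A nonnegative coupling with its two marginals.

    ``row_marginal`` is ``P @ 1`` (mass leaving each source bin) and
    ``col_marginal`` is ``P.T @ 1`` (mass arriving at each target bin); they are
    computed once at construction. ``converged`` is False when an iterative
    solver hit its iteration cap before reaching its tolerance.
    """

    P: np.ndarray
    row_marginal: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_marginal: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2:
            raise DimensionError("transport plan must be a matrix")
        if np.any(P < -1e-15):
            raise ValueError("transport plan has negative entries")
        object.__setattr__(self, "P", P)
        if self.row_marginal is None:
            object.__setattr__(self, "row_marginal", P.sum(axis=1))
        if self.col_marginal is None:
            object.__setattr__(self, "col_marginal", P.sum(axis=0))

    @property
    def mass(self) -> float:
        return float(self.P.sum())


def generalized_kl(x, y) -> float:
    """Generalized Kullback-Leibler divergence between nonnegative arrays.

    ``KL(x, y) = <x, log(x / y)> + <y - x, 1>``, with ``0 log 0 = 0``. Unlike
    the probability-simplex KL this is finite and meaningful for unnormalized
    measures; it is zero iff ``x == y`` and ``+inf`` when ``x`` carries mass
    where ``y`` has none.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(f"shape mismatch: {x.shape} vs {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("generalized KL requires nonnegative arguments")
    pos = x > 0
    if np.any(pos & (y == 0)):
        return float("inf")
    xs = x[pos]
    val = float(np.sum(xs * np.log(xs / y[pos])) + y.sum() - x.sum())
    return val


def build_ground_cost(n: int, mode: str = "index", Y=None) -> np.ndarray:
    """Construct an ``n x n`` ground-cost matrix over score-space bins.

    mode="index" places bin ``j`` at coordinate ``j/(n-1)`` on a line and uses
    squared distance, so ``C[j, k] = (j - k)^2 / (n - 1)^2``. mode="data"
    measures squared Euclidean distance between the standardized columns of the
    score matrix ``Y`` and rescales by the largest off-diagonal entry. Either
    way the result is symmetric, zero-diagonal, with max entry 1.
    """
    if n < 2:
        raise ConfigError("ground cost needs n >= 2 bins")
    if mode == "index":
        idx = np.arange(n, dtype=float)
        C = np.subtract.outer(idx, idx) ** 2 / (n - 1) ** 2
        return C
    if mode == "data":
        if Y is None:
            raise ConfigError("mode='data' requires a score matrix Y")
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != n:
            raise ConfigError(f"Y must have {n} columns, got shape {Y.shape}")
        if Y.shape[0] < 2:
            raise ConfigError("mode='data' requires at least 2 samples")
        sd = Y.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ConfigError(f"score column {bad} is constant; cannot standardize")
        Ys = (Y - Y.mean(axis=0)) / sd
        sq = np.sum(Ys**2, axis=0)
        C = sq[:, None] + sq[None, :] - 2.0 * (Ys.T @ Ys)
        C = np.maximum(C, 0.0)
        np.fill_diagonal(C, 0.0)
        C = 0.5 * (C + C.T)
        off_max = C.max()
        if off_max > 0:
            C = C / off_max
        return C
    raise ConfigError(f"unknown ground-cost mode {mode!r}")


def _check_cost(C, n_a: int, n_b: int) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (n_a, n_b):
        raise DimensionError(f"cost matrix shape {C.shape} != ({n_a}, {n_b})")
    return C


def exact_ot(a, b, C) -> tuple[TransportPlan, float]:
    """Solve the transport linear program exactly (the oracle for all solvers).

    Minimizes ``<C, P>`` over nonnegative couplings with row marginal ``a`` and
    column marginal ``b``; the two measures must have the same positive total
    mass. Returns the optimal plan and the transport cost (the Wasserstein
    value for ``C`` a metric cost).
    """
    a = _as_mass_vector(a, "source measure")
    b = _as_mass_vector(b, "target measure")
    C = _check_cost(C, a.size, b.size)
    ma, mb = a.sum(), b.sum()
    if abs(ma - mb) > 1e-9:
        raise BalanceError(f"mass mismatch: {ma} vs {mb}")
    if ma <= 0:
        raise BalanceError("exact OT requires positive total mass")
    na, nb = a.size, b.size
    # equality constraints: row sums = a, col sums = b (last row dropped: redundant)
    rows = np.kron(np.eye(na), np.ones((1, nb)))
    cols = np.kron(np.ones((1, na)), np.eye(nb))
    A_eq = np.vstack([rows, cols])[:-1]
    b_eq = np.concatenate([a, b])[:-1]
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise SolverError(f"transport LP failed: {res.message}")
    P = np.maximum(res.x.reshape(na, nb), 0.0)
    return TransportPlan(P), float(res.fun)


def _entropy_value(P: np.ndarray, C: np.ndarray, gamma: float) -> float:
    """Entropy-smoothed transport value ``<C, P> - gamma * e(P)``."""
    pos = P > 0
    ent = -float(np.sum(P[pos] * np.log(P[pos])))
    return float(np.sum(C * P)) - gamma * ent


def sinkhorn_balanced(a, b, C, gamma: float, tol: float = 1e-9,
                      max_iter: int = 10_000) -> tuple[TransportPlan, float]:
    """Entropic OT between mass-balanced measures via Sinkhorn-Knopp scaling.

    Alternates ``u <- a / (K v)`` and ``v <- b / (K^T u)`` on the Gibbs kernel
    ``K = exp(-C / gamma)`` until the worst marginal violation drops below
    ``tol``. Returns ``P = diag(u) K diag(v)`` and the smoothed value
    ``<C, P> - gamma * e(P)`` with ``e`` the (negative) Boltzmann entropy.
    For ``gamma`` below 1e-2 the iteration runs in the log domain to dodge
    kernel underflow.
    """
    a = _as_mass_vector(a, "source measure")
    b = _as_mass_vector(b, "target measure")
    C = _check_cost(C, a.size, b.size)
    if gamma <= 0:
        raise ConfigError("gamma must be positive")
    ma, mb = a.sum(), b.sum()
    if ma <= 0 or mb <= 0:
        raise BalanceError("balanced Sinkhorn requires positive mass")
    if abs(ma - mb) > 1e-9:
        raise BalanceError(f"mass mismatch: {ma} vs {mb}")

    n_iter = 0
    converged = False
    if gamma >= _LOG_DOMAIN_GAMMA:
        K = np.exp(-C / gamma)
        u = np.ones_like(a)
        v = np.ones_like(b)
        for n_iter in range(1, max_iter + 1):
            u = a / np.maximum(K @ v, _SCALE_FLOOR)
            v = b / np.maximum(K.T @ u, _SCALE_FLOOR)
            # after the v-update column marginals are exact; check the rows
            viol = np.max(np.abs(u * (K @ v) - a))
            if viol < tol:
                converged = True
                break
        P = u[:, None] * K * v[None, :]
    else:
        # log-domain: potentials phi = log u, psi = log v
        with np.errstate(divide="ignore"):
            la, lb = np.log(a), np.log(b)
        M = -C / gamma
        phi = np.zeros_like(a)
        psi = np.zeros_like(b)
        for n_iter in range(1, max_iter + 1):
            phi = la - logsumexp(M + psi[None, :], axis=1)
            psi = lb - logsumexp(M + phi[:, None], axis=0)
            P = np.exp(M + phi[:, None] + psi[None, :])
            viol = np.max(np.abs(P.sum(axis=1) - a))
            if viol < tol:
                converged = True
                break
        P = np.exp(M + phi[:, None] + psi[None, :])
    return TransportPlan(P, converged=converged, n_iter=n_iter), _entropy_value(P, C, gamma)


def relaxed_objective(P: np.ndarray, K: np.ndarray, a, b,
                      gamma: float, mu: float) -> float:
    """KL-relaxed transport objective ``gamma KL(P|K) + mu KL(P1|a) + mu KL(P'1|b)``."""
    P = np.asarray(P, dtype=float)
    return float(
        gamma * generalized_kl(P, K)
        + mu * generalized_kl(P.sum(axis=1), np.asarray(a, dtype=float))
        + mu * generalized_kl(P.sum(axis=0), np.asarray(b, dtype=float))
    )


def sinkhorn_relaxed(a, b, C, gamma: float, mu: float, tol: float = 1e-9,
                     max_iter: int = 10_000) -> tuple[TransportPlan, float]:
    """Unbalanced entropic OT with KL-penalized marginals.

    Minimizes ``f(P) = gamma KL(P|K) + mu KL(P1 | a) + mu KL(P'1 | b)`` where
    ``K = exp(-C/gamma)``. The hard marginal constraints of balanced transport
    are replaced by KL penalties of weight ``mu``, so the two measures may have
    different — even zero — total mass. Solved by the generalized scaling
    iteration ``u <- (a / K v)^rho``, ``v <- (b / K^T u)^rho`` with
    ``rho = mu / (mu + gamma)``; as ``mu -> inf`` this recovers the balanced
    Sinkhorn fixed point, and at ``mu = 0`` the minimizer is ``K`` itself.

    A measure that is identically zero forces ``P = 0`` (any transported mass
    would make its KL term infinite); that case is returned in closed form with
    value ``gamma * sum(K) + mu * (mass(a) + mass(b))``.
    """
    a = _as_mass_vector(a, "source measure")
    b = _as_mass_vector(b, "target measure")
    C = _check_cost(C, a.size, b.size)
    if gamma <= 0:
        raise ConfigError("gamma must be positive")
    if mu < 0:
        raise ConfigError("mu must be nonnegative")
    K = np.exp(-C / gamma)
    if mu == 0:
        return TransportPlan(K.copy(), n_iter=0), 0.0
    if a.sum() == 0 or b.sum() == 0:
        P = np.zeros_like(K)
        value = gamma * K.sum() + mu * (a.sum() + b.sum())
        return TransportPlan(P, n_iter=0), float(value)

    rho = mu / (mu + gamma)
    n_iter = 0
    converged = False
    if gamma >= _LOG_DOMAIN_GAMMA:
        u = np.ones_like(a)
        v = np.ones_like(b)
        for n_iter in range(1, max_iter + 1):
            u_new = (a / np.maximum(K @ v, _SCALE_FLOOR)) ** rho
            v_new = (b / np.maximum(K.T @ u_new, _SCALE_FLOOR)) ** rho
            err = max(
                np.max(np.abs(u_new - u)) / (1.0 + np.max(np.abs(u_new))),
                np.max(np.abs(v_new - v)) / (1.0 + np.max(np.abs(v_new))),
            )
            u, v = u_new, v_new
            if err < tol:
                converged = True
                break
        P = u[:, None] * K * v[None, :]
    else:
        with np.errstate(divide="ignore"):
            la, lb = np.log(a), np.log(b)
        M = -C / gamma
        phi = np.zeros_like(a)
        psi = np.zeros_like(b)
        for n_iter in range(1, max_iter + 1):
            phi_new = rho * (la - logsumexp(M + psi[None, :], axis=1))
            psi_new = rho * (lb - logsumexp(M + phi_new[:, None], axis=0))
            err = max(_pot_change(phi_new, phi), _pot_change(psi_new, psi))
            phi, psi = phi_new, psi_new
            if err < tol:
                converged = True
                break
        P = np.exp(M + phi[:, None] + psi[None, :])
    value = relaxed_objective(P, K, a, b, gamma, mu)
    return TransportPlan(P, converged=converged, n_iter=n_iter), value


def _pot_change(new: np.ndarray, old: np.ndarray) -> float:
    """Sup-norm change of a log-domain potential, ignoring -inf entries."""
    finite = np.isfinite(new) & np.isfinite(old)
    if not np.any(finite):
        return 0.0
    scale = 1.0 + np.max(np.abs(new[finite]))
    return float(np.max(np.abs(new[finite] - old[finite])) / scale)


# ---------------------------------------------------------------------------
# batched relaxed Sinkhorn (shared kernel, many marginal pairs) — used by the
# regression model, where every sample row induces one small transport problem
# ---------------------------------------------------------------------------

def sinkhorn_relaxed_batch(A_src: np.ndarray, B_tgt: np.ndarray, C: np.ndarray,
                           gamma: float, mu: float, tol: float = 1e-9,
                           max_iter: int = 10_000):
    """Solve many KL-relaxed transport problems sharing one ground cost.

    ``A_src`` and ``B_tgt`` are ``n x B`` arrays whose columns are the source
    and target measures of ``B`` independent problems (all entries must be
    strictly positive — the model guarantees this via its weight floor and
    score scaling). Returns ``(U, V, K, converged, n_iter)`` with the plans
    recoverable as ``P_b = diag(U[:, b]) K diag(V[:, b])``.
    """
    if gamma <= 0:
        raise ConfigError("gamma must be positive")
    if mu <= 0:
        raise ConfigError("batched solver requires mu > 0")
    A_src = np.asarray(A_src, dtype=float)
    B_tgt = np.asarray(B_tgt, dtype=float)
    if A_src.shape != B_tgt.shape:
        raise DimensionError("source/target batches must have equal shape")
    n = A_src.shape[0]
    C = _check_cost(C, n, n)
    if np.any(A_src <= 0) or np.any(B_tgt <= 0):
        raise ValueError("batched solver requires strictly positive marginals")
    rho = mu / (mu + gamma)
    converged = False
    if gamma >= _LOG_DOMAIN_GAMMA:
        K = np.exp(-C / gamma)
        U = np.ones_like(A_src)
        V = np.ones_like(B_tgt)
        for n_iter in range(1, max_iter + 1):
            U_new = (A_src / np.maximum(K @ V, _SCALE_FLOOR)) ** rho
            V_new = (B_tgt / np.maximum(K.T @ U_new, _SCALE_FLOOR)) ** rho
            err = max(
                np.max(np.abs(U_new - U)) / (1.0 + np.max(np.abs(U_new))),
                np.max(np.abs(V_new - V)) / (1.0 + np.max(np.abs(V_new))),
            )
            U, V = U_new, V_new
            if err < tol:
                converged = True
                break
    else:
        M = -C / gamma
        K = np.exp(M)
        LA, LB = np.log(A_src), np.log(B_tgt)
        Phi = np.zeros_like(A_src)
        Psi = np.zeros_like(B_tgt)
        for n_iter in range(1, max_iter + 1):
            Phi_new = rho * (LA - logsumexp(M[:, :, None] + Psi[None, :, :], axis=1))
            Psi_new = rho * (LB - logsumexp(M.T[:, :, None] + Phi_new[None, :, :], axis=1))
            err = max(_pot_change(Phi_new, Phi), _pot_change(Psi_new, Psi))
            Phi, Psi = Phi_new, Psi_new
            if err < tol:
                converged = True
                break
        U, V = np.exp(Phi), np.exp(Psi)
    return U, V, K, converged, n_iter


def batch_plans(U: np.ndarray, V: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Materialize batched plans as a ``B x n x n`` array."""
    return U.T[:, :, None] * K[None, :, :] * V.T[:, None, :]


def batch_row_marginals(U: np.ndarray, V: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Row marginals ``P_b @ 1`` of the batched plans, as ``n x B``."""
    return U * (K @ V)


def batch_values(U: np.ndarray, V: np.ndarray, K: np.ndarray,
                 A_src: np.ndarray, B_tgt: np.ndarray,
                 gamma: float, mu: float) -> np.ndarray:
    """Relaxed objective value of each batched plan (length-``B`` array).

    Uses ``KL(P|K) = <P, log u + log v> + sum(K) - sum(P)`` which is exact for
    plans of the scaling form and avoids forming ``log P`` where ``P`` vanishes.
    """
    with np.errstate(divide="ignore"):
        logU = np.where(U > 0, np.log(np.maximum(U, _SCALE_FLOOR)), 0.0)
        logV = np.where(V > 0, np.log(np.maximum(V, _SCALE_FLOOR)), 0.0)
    row = batch_row_marginals(U, V, K)            # n x B
    col = V * (K.T @ U)                           # n x B
    mass = row.sum(axis=0)                        # B
    kl_pk = (row * logU).sum(axis=0) + (col * logV).sum(axis=0) + K.sum() - mass
    kl_row = _gkl_cols(row, A_src)
    kl_col = _gkl_cols(col, B_tgt)
    return gamma * kl_pk + mu * kl_row + mu * kl_col


def _gkl_cols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise generalized KL for strictly positive reference columns."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(np.maximum(X, _SCALE_FLOOR) / Y), 0.0)
    return term.sum(axis=0) + Y.sum(axis=0) - X.sum(axis=0)
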
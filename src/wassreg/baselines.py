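"""Reference regression models: ridge (multi-output least squares with
Frobenius penalty) and l2,1-norm joint feature selection.

Both share the data layout of the transport-based model — features x samples
``A``, samples x tasks ``Y``, weights ``Z`` of shape features x tasks — so the
evaluation harness can treat every selector uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ValidationError
from .selection import FeatureRanking, rank_features

__all__ = ["RidgeResults", "L21Results", "ridge_fit", "l21_fs_fit"]

#: smoothing floor on row norms in the IRLS reweighting
_IRLS_FLOOR = 1e-8


def _check_shapes(A, Y):
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if A.ndim != 2 or Y.ndim != 2:
        raise DimensionError("A and Y must be matrices")
    if A.shape[1] != Y.shape[0]:
        raise DimensionError(
            f"A has {A.shape[1]} samples but Y has {Y.shape[0]} rows")
    return A, Y


@dataclass(frozen=True)
class RidgeResults:
    """Closed-form ridge solution ``Z = (A A' + lam I)^-1 A Y``."""

    Z: np.ndarray
    lam: float
    intercept: np.ndarray | None = None
    feature_names: tuple | None = None

    def predict(self, A_new) -> np.ndarray:
        pred = np.asarray(A_new, dtype=float).T @ self.Z
        if self.intercept is not None:
            pred = pred + self.intercept
        return pred

    def rank_features(self, names=None) -> FeatureRanking:
        names = names if names is not None else (
            self.feature_names or range(self.Z.shape[0]))
        return rank_features(self.Z, names)


def ridge_fit(A, Y, lam: float, fit_intercept: bool = False,
              feature_names=None) -> RidgeResults:
    """Minimize ``||Y - A'Z||_F^2 + lam ||Z||_F^2`` in closed form.

    Solves the normal equations ``(A A' + lam I) Z = A Y``. ``lam = 0`` is
    allowed only when ``A A'`` is invertible (checked via Cholesky).
    With ``fit_intercept=True`` an unpenalized per-task intercept is added by
    centering — the standard choice for a prediction harness, where the target
    mean should not be shrunk away.
    """
    A, Y = _check_shapes(A, Y)
    if lam < 0:
        raise ValidationError("lam must be nonnegative")
    m = A.shape[0]
    if fit_intercept:
        a_bar = A.mean(axis=1, keepdims=True)
        y_bar = Y.mean(axis=0, keepdims=True)
        Ac, Yc = A - a_bar, Y - y_bar
    else:
        Ac, Yc = A, Y
    G = Ac @ Ac.T + lam * np.eye(m)
    try:
        cho = np.linalg.cholesky(G)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"normal equations singular (lam={lam}); use lam > 0") from exc
    Z = np.linalg.solve(cho.T, np.linalg.solve(cho, Ac @ Yc))
    intercept = (y_bar - a_bar.T @ Z).ravel() if fit_intercept else None
    return RidgeResults(Z=Z, lam=float(lam), intercept=intercept,
                        feature_names=tuple(feature_names) if feature_names else None)


@dataclass(frozen=True)
class L21Results:
    """IRLS solution of the doubly l2,1 objective with its trace."""

    Z: np.ndarray
    lam: float
    objective_trace: np.ndarray
    converged: bool

    def rank_features(self, names=None) -> FeatureRanking:
        names = names if names is not None else range(self.Z.shape[0])
        return rank_features(self.Z, names)


def _l21_smoothed(M: np.ndarray) -> float:
    return float(np.sum(np.sqrt(np.sum(M * M, axis=1) + _IRLS_FLOOR**2)))


def l21_fs_fit(A, Y, lam: float, tol: float = 1e-8, max_iter: int = 1000) -> L21Results:
    """Minimize ``||Y - A'Z||_{2,1} + lam ||Z||_{2,1}`` by reweighted least squares.

    Each sweep reweights both terms by inverse (smoothed) row norms — residual
    rows of the loss, weight rows of the penalty — and solves the resulting
    weighted ridge system. The smoothed objective (row norms replaced by
    ``sqrt(||.||^2 + 1e-16)``) is non-increasing across sweeps; iteration stops
    when its relative change falls below ``tol``.
    """
    A, Y = _check_shapes(A, Y)
    if lam <= 0:
        raise ValidationError("l2,1 selection requires lam > 0")
    m, l = A.shape
    Z = ridge_fit(A, Y, lam=lam).Z
    trace = [_l21_smoothed(Y - A.T @ Z) + lam * _l21_smoothed(Z)]
    converged = False
    for _ in range(max_iter):
        R = Y - A.T @ Z
        dr = 0.5 / np.sqrt(np.sum(R * R, axis=1) + _IRLS_FLOOR**2)   # per sample
        dz = 0.5 / np.sqrt(np.sum(Z * Z, axis=1) + _IRLS_FLOOR**2)   # per feature
        G = (A * dr[None, :]) @ A.T + lam * np.diag(dz)
        Z = np.linalg.solve(G, (A * dr[None, :]) @ Y)
        obj = _l21_smoothed(Y - A.T @ Z) + lam * _l21_smoothed(Z)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    return L21Results(Z=Z, lam=float(lam),
                      objective_trace=np.asarray(trace), converged=converged)
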
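"""Soft-margin support vector machines (linear and RBF kernels).

The classifier solves the boxed dual of the maximum-margin problem,

    max_a  sum_i a_i - 1/2 sum_{ij} a_i a_j Y_i Y_j K(X_i, X_j)
    s.t.   sum_i a_i Y_i = 0,  0 <= a_i <= C,

via libsvm's SMO (scikit-learn's SVC).  The module exposes the full dual
coefficient vector, intercept and support set, and computes decision values
through the representer form sum_i a_i Y_i K(X_i, x) + b so that the fitted
object is self-contained.  The RBF kernel uses the scale convention
K(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["KernelSpec", "SvmModel", "svm_fit", "svm_fit_precomputed", "svm_decision"]

_JITTER = 1e-10  # diagonal regularization for degenerate precomputed kernels


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and scale.  ``kind`` in {"linear", "rbf", "precomputed"}."""

    kind: str = "linear"
    sigma: float | None = None

    def gamma(self) -> float:
        if self.kind != "rbf":
            raise ValueError("gamma only defined for rbf kernels")
        if self.sigma is None or self.sigma <= 0:
            raise ValueError("rbf kernel requires sigma > 0")
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class SvmModel:
    """A fitted SVM: dual coefficients, intercept and cached training rows."""

    alpha: np.ndarray  # one nonnegative coefficient per training subject
    b: float
    C: float
    kernel: KernelSpec
    X_train: np.ndarray | None  # None for precomputed-kernel models
    y_train: np.ndarray
    support_: np.ndarray

    @property
    def W(self) -> np.ndarray:
        """Explicit primal weights (linear kernel only)."""
        if self.kernel.kind != "linear":
            raise ValueError("explicit weights exist only for the linear kernel")
        return (self.alpha * self.y_train) @ self.X_train

    def dual_objective(self, K: np.ndarray | None = None) -> float:
        """Value of the dual objective at the fitted coefficients."""
        if K is None:
            K = _kernel_matrix(self.kernel, self.X_train, self.X_train)
        ay = self.alpha * self.y_train
        return float(self.alpha.sum() - 0.5 * ay @ K @ ay)


def _kernel_matrix(kernel: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if kernel.kind == "linear":
        return A @ B.T
    if kernel.kind == "rbf":
        return np.exp(-kernel.gamma() * cdist(A, B, "sqeuclidean"))
    raise ValueError(f"cannot build kernel matrix for {kernel.kind!r}")


def _extract(svc: SVC, y: np.ndarray, C: float) -> tuple[np.ndarray, float, np.ndarray]:
    n = len(y)
    alpha = np.zeros(n)
    # classes_ is sorted [-1, +1]; dual_coef_ holds alpha_i * y_i
    dual = svc.dual_coef_[0]
    alpha[svc.support_] = np.abs(dual)
    if np.any(alpha > C + 1e-8):
        raise RuntimeError("solver returned coefficients above the box constraint")
    b = float(svc.intercept_[0])
    return alpha, b, svc.support_.copy()


def svm_fit(X: np.ndarray, y: np.ndarray, kernel=None, C: float = 1.0, tol: float = 1e-3) -> SvmModel:
    """Fit a soft-margin SVM.

    ``kernel`` may be a KernelSpec or one of "linear"/"rbf" (the latter
    requires ``KernelSpec(kind="rbf", sigma=...)`` for a non-default scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if isinstance(kernel, str):
        kernel = KernelSpec(kind=kernel)
    if kernel is None:
        kernel = KernelSpec()
    if C <= 0:
        raise ValueError("C must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if kernel.kind == "linear":
        svc = SVC(kernel="linear", C=C, tol=tol)
    elif kernel.kind == "rbf":
        svc = SVC(kernel="rbf", C=C, gamma=kernel.gamma(), tol=tol)
    else:
        raise ValueError(f"unsupported kernel {kernel.kind!r} for svm_fit")
    svc.fit(X, y)
    alpha, b, support = _extract(svc, y, C)
    return SvmModel(
        alpha=alpha, b=b, C=C, kernel=kernel, X_train=X, y_train=y, support_=support
    )


def svm_fit_precomputed(K: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-3) -> SvmModel:
    """Fit on a precomputed Gram matrix (used by multiple kernel learning).

    A 1e-10 diagonal jitter guards against rank-degenerate kernels.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=int)
    Kj = K + _JITTER * np.eye(K.shape[0])
    logger.debug("precomputed kernel fit with %g diagonal jitter", _JITTER)
    svc = SVC(kernel="precomputed", C=C, tol=tol)
    svc.fit(Kj, y)
    alpha, b, support = _extract(svc, y, C)
    return SvmModel(
        alpha=alpha, b=b, C=C, kernel=KernelSpec(kind="precomputed"),
        X_train=None, y_train=y, support_=support,
    )


def svm_decision(model: SvmModel, X_new: np.ndarray) -> np.ndarray:
    """Signed decision values sum_i alpha_i Y_i K(X_i, x) + b per row of X_new.

    For precomputed-kernel models ``X_new`` must be the n_new x n_train
    cross-kernel matrix.
    """
    X_new = np.asarray(X_new, dtype=float)
    ay = model.alpha * model.y_train
    if model.kernel.kind == "precomputed":
        if X_new.shape[1] != len(model.y_train):
            raise ValueError("cross-kernel column count must equal training size")
        return X_new @ ay + model.b
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature count {X_new.shape[1]} does not match training "
            f"count {model.X_train.shape[1]}"
        )
    K = _kernel_matrix(model.kernel, X_new, model.X_train)
    return K @ ay + model.b
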
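"""Elastic-net regularized logistic regression (GLM) and LASSO sparse sets.

The model minimizes the penalized average negative log-likelihood

    f(b0, b) = -(1/N) sum_i [ y_i log h_i + (1 - y_i) log(1 - h_i) ]
               + lambda * [ (1 - alpha)/2 ||b||_2^2 + alpha ||b||_1 ],

with h_i = 1 / (1 + exp(-(b0 + x_i' b))), labels y in {0, 1}, an
unpenalized intercept, elasticity alpha in (0, 1] (alpha -> 0 approaches
ridge, alpha = 1 is the LASSO) and penalty strength lambda >= 0.  The
solver is IRLS with coordinate-descent inner sweeps (soft-thresholding),
started from zero and damped so the penalized objective is non-increasing
across outer iterations.  At alpha = 1 and lambda >= lambda_max the
solution collapses exactly to b = 0, b0 = logit(prevalence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data import FeatureTable, SplitPlan, standardize, stratified_kfold
from .metrics import roc_auc

__all__ = [
    "GlmModel",
    "glm_fit",
    "glm_path",
    "glm_decision",
    "lambda_max",
    "lasso_minimal_set",
    "LassoReport",
]

_WEIGHT_FLOOR = 1e-5  # IRLS working-weight floor near saturated probabilities


@dataclass
class GlmModel:
    beta: np.ndarray
    intercept: float
    lam: float
    alpha: float
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _objective(X, y, b0, beta, lam, alpha) -> float:
    eta = b0 + X @ beta
    # -log likelihood via log(1 + exp(.)) stable form
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen = lam * ((1 - alpha) / 2 * float(beta @ beta) + alpha * float(np.abs(beta).sum()))
    return nll + pen


@njit(cache=False)
def _cd_sweeps(
    X, Xw, w, resid, beta, b0, wx2, denom, thresh, w_sum, active, max_sweeps, tol
):
    """Cyclic coordinate-descent sweeps over ``active`` on the weighted
    quadratic surrogate; updates resid/beta in place, returns new intercept."""
    N = X.shape[0]
    for _ in range(max_sweeps):
        max_delta = 0.0
        num = 0.0
        for i in range(N):
            num += w[i] * resid[i]
        d0 = num / w_sum  # unpenalized intercept step
        if d0 != 0.0:
            b0 += d0
            for i in range(N):
                resid[i] -= d0
            max_delta = abs(d0)
        for jj in range(active.shape[0]):
            j = active[jj]
            rho = 0.0
            for i in range(N):
                rho += Xw[i, j] * resid[i]
            rho = rho / N + wx2[j] * beta[j]
            if rho > thresh:
                new = (rho - thresh) / denom[j]
            elif rho < -thresh:
                new = (rho + thresh) / denom[j]
            else:
                new = 0.0
            d = new - beta[j]
            if d != 0.0:
                for i in range(N):
                    resid[i] -= X[i, j] * d
                beta[j] = new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            break
    return b0


def glm_fit(
    X: np.ndarray,
    y01: np.ndarray,
    lam: float,
    alpha: float,
    max_iter: int = 200,
    tol: float = 1e-7,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> GlmModel:
    """Coordinate-descent fit of the elastic-net logistic objective.

    Deterministic from zero initialization (or an explicit warm start).
    Perfect separation at lambda = 0 is caught by the iteration cap with a
    warning rather than divergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must lie in {0, 1}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    N, P = X.shape
    if warm_start is None:
        b0, beta = 0.0, np.zeros(P)
    else:
        b0, beta = float(warm_start[0]), np.asarray(warm_start[1], dtype=float).copy()

    obj = _objective(X, y, b0, beta, lam, alpha)
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b0_old, beta_old = b0, beta.copy()
        eta = b0 + X @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1.0 - p), _WEIGHT_FLOOR, None)
        z = eta + (y - p) / w
        # coordinate sweeps on the weighted quadratic surrogate; after a
        # full sweep, iterate on the active (nonzero) set only
        XF = np.asfortranarray(X)
        Xw = np.asfortranarray(X * w[:, None])
        wx2 = (X * X * w[:, None]).mean(axis=0)
        denom = wx2 + lam * (1 - alpha)
        thresh = lam * alpha
        w_sum = float(w.sum())
        resid = z - b0 - X @ beta
        all_idx = np.arange(P, dtype=np.int64)

        b0 = _cd_sweeps(
            XF, Xw, w, resid, beta, b0, wx2, denom, thresh, w_sum, all_idx, 1, 0.0
        )
        for _ in range(100):
            active = np.flatnonzero(beta)
            b0 = _cd_sweeps(
                XF, Xw, w, resid, beta, b0, wx2, denom, thresh, w_sum,
                active, 100, 1e-10,
            )
            # converged when a fresh full sweep moves nothing
            b0_before, beta_before = b0, beta.copy()
            b0 = _cd_sweeps(
                XF, Xw, w, resid, beta, b0, wx2, denom, thresh, w_sum,
                all_idx, 1, 0.0,
            )
            moved = max(abs(b0 - b0_before), float(np.max(np.abs(beta - beta_before))))
            if moved < 1e-10:
                break
        # damp the IRLS step if the true objective increased
        new_obj = _objective(X, y, b0, beta, lam, alpha)
        step = 1.0
        while new_obj > obj + 1e-12 and step > 1e-6:
            step *= 0.5
            b0 = b0_old + step * (b0 - b0_old)
            beta = beta_old + step * (beta - beta_old)
            new_obj = _objective(X, y, b0, beta, lam, alpha)
        if new_obj > obj + 1e-12:  # could not decrease; accept previous iterate
            b0, beta = b0_old, beta_old
            converged = True
            break
        delta = obj - new_obj
        obj = new_obj
        path.append(obj)
        if delta <= tol * max(1.0, abs(obj)):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GLM did not converge in {max_iter} iterations "
            "(possible perfect separation at small lambda)",
            stacklevel=2,
        )
    return GlmModel(
        beta=beta, intercept=b0, lam=lam, alpha=alpha,
        converged=converged, n_iter=it, objective_path=path,
    )


def glm_decision(model: GlmModel, X: np.ndarray) -> np.ndarray:
    """Linear predictor (log-odds); sigmoid of this is the probability."""
    return model.intercept + np.asarray(X, dtype=float) @ model.beta


def lambda_max(X: np.ndarray, y01: np.ndarray, alpha: float = 1.0) -> float:
    """Smallest lambda at which all coefficients are zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float)
    pbar = y.mean()
    grad = X.T @ (y - pbar) / len(y)
    return float(np.max(np.abs(grad)) / max(alpha, 1e-3))


def glm_path(
    X: np.ndarray, y01: np.ndarray, lambdas: np.ndarray, alpha: float, **kwargs
) -> list[GlmModel]:
    """Warm-started fits along a descending lambda path."""
    order = np.argsort(lambdas)[::-1]
    models: dict[int, GlmModel] = {}
    warm = None
    for idx in order:
        m = glm_fit(X, y01, float(lambdas[idx]), alpha, warm_start=warm, **kwargs)
        warm = (m.intercept, m.beta)
        models[int(idx)] = m
    return [models[i] for i in range(len(lambdas))]


@dataclass
class LassoReport:
    """Sparse predictor set found by L1-regularized logistic regression."""

    features: list[str]
    by_modality: dict[str, list[str]]
    coefficients: dict[str, float]
    lam: float
    outer_auc_mean: float
    outer_auc_sd: float
    outer_aucs: list[float]


def _cv_choose_lambda(X, y01, lambdas, k, seed, alpha=1.0) -> float:
    """Inner-CV lambda by the one-standard-error rule.

    The mean validation AUC is computed along the lambda path; among values
    within one standard error of the maximum, the largest lambda (sparsest
    model) is chosen — the standard parsimony rule for minimal predictor
    sets, since the AUC curve is typically flat over a wide lambda range.
    """
    y_pm = np.where(y01 == 1, 1, -1)
    plan = stratified_kfold(y_pm, k=k, seed=seed)
    aucs = np.zeros((k, len(lambdas)))
    for f, (tr, va) in enumerate(plan.folds):
        models = glm_path(X[tr], y01[tr], lambdas, alpha=alpha)
        for i, m in enumerate(models):
            scores = glm_decision(m, X[va])
            aucs[f, i] = roc_auc(scores, y_pm[va]) if len(np.unique(y_pm[va])) > 1 else 0.5
    mean = aucs.mean(axis=0)
    best = int(np.argmax(mean))
    se_best = float(aucs[:, best].std(ddof=0) / np.sqrt(k))
    candidates = np.flatnonzero(mean >= mean[best] - se_best)
    return float(lambdas[candidates[np.argmax(lambdas[candidates])]])


def lasso_minimal_set(
    table: FeatureTable,
    splits: SplitPlan | None = None,
    inner_k: int = 5,
    n_lambda: int = 25,
    seed: int = 0,
) -> LassoReport:
    """Minimal predictor set via LASSO (alpha = 1) with nested CV.

    Per outer fold, features are standardized on the training rows, lambda
    is chosen by inner-CV maximal mean AUC, and the held-out AUC of the
    refit model is recorded.  The reported feature set comes from a final
    fit on the full table at a lambda chosen by CV on all rows; features
    with nonzero coefficients are grouped by modality.
    """
    table.validate()
    if splits is None:
        splits = stratified_kfold(table.y, k=5, seed=seed)
    y01 = (table.y == 1).astype(float)

    outer_aucs = []
    for f, (tr, te) in enumerate(splits.folds):
        std, _ = standardize(table, reference=tr)
        Xs = std.X
        lmax = lambda_max(Xs[tr], y01[tr])
        lambdas = np.geomspace(lmax, lmax * 1e-3, n_lambda)
        lam = _cv_choose_lambda(Xs[tr], y01[tr], lambdas, k=inner_k, seed=seed + 31 * f)
        model = glm_fit(Xs[tr], y01[tr], lam, alpha=1.0)
        scores = glm_decision(model, Xs[te])
        outer_aucs.append(roc_auc(scores, table.y[te]))

    # final fit on all rows
    std, _ = standardize(table)
    lmax = lambda_max(std.X, y01)
    lambdas = np.geomspace(lmax, lmax * 1e-3, n_lambda)
    lam = _cv_choose_lambda(std.X, y01, lambdas, k=inner_k, seed=seed + 977)
    final = glm_fit(std.X, y01, lam, alpha=1.0)
    nonzero = np.flatnonzero(final.beta != 0.0)
    if nonzero.size == 0:
        warnings.warn("LASSO selected no features at any lambda", stacklevel=2)
    features = [table.feature_names[i] for i in nonzero]
    by_modality: dict[str, list[str]] = {}
    for name in features:
        by_modality.setdefault(table.modality_map.get(name, "unknown"), []).append(name)
    coefficients = {
        table.feature_names[i]: float(final.beta[i]) for i in nonzero
    }
    arr = np.asarray(outer_aucs)
    return LassoReport(
        features=features,
        by_modality=by_modality,
        coefficients=coefficients,
        lam=lam,
        outer_auc_mean=float(arr.mean()),
        outer_auc_sd=float(arr.std()),
        outer_aucs=[float(a) for a in arr],
    )
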
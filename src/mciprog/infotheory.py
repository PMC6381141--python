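"""Plug-in mutual information and greedy JMI forward feature selection.

Mutual information between discrete variables Q and R,

    I(Q;R) = sum_{q,r} p(q,r) log2 p(q,r) / (p(q) p(r)),

is estimated by the plug-in rule from empirical cell frequencies (0*log 0
taken as 0, base-2 logs).  Continuous features are discretized into
equal-frequency bins whose edges are learned on training rows.

Feature selection uses the joint-mutual-information criterion: starting
from the single feature maximizing I(F;Y), each step adds the candidate
maximizing sum_{j in selected} I(candidate, F_j; Y), where (candidate, F_j)
is the product-alphabet joint variable.  This pairwise form is the standard
practical JMI selector; it rewards features that are informative about the
label jointly with what is already selected, and so avoids redundant picks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscretizedFeature",
    "discretize",
    "discretize_matrix",
    "mutual_information",
    "entropy",
    "joint_variable",
    "jmi_score",
    "jmi_select",
    "SelectionResult",
]


@dataclass
class DiscretizedFeature:
    """Integer codes per subject plus the quantile edges that produced them."""

    codes: np.ndarray  # values in [0, n_levels)
    n_levels: int
    edges: np.ndarray  # interior bin edges, monotone non-decreasing

    def __len__(self) -> int:
        return len(self.codes)


def discretize(
    values: np.ndarray, bins: int = 5, fit_values: np.ndarray | None = None
) -> DiscretizedFeature:
    """Equal-frequency discretization.

    Interior edges are the (1/bins, ..., (bins-1)/bins) quantiles of
    ``fit_values`` (defaults to ``values``; pass training rows to avoid
    leaking held-out rows into the edges).  Features with at most ``bins``
    distinct fitted values (binary indicators, small discrete alphabets)
    pass through with one code per level, split at level midpoints.
    """
    values = np.asarray(values, dtype=float)
    fit = values if fit_values is None else np.asarray(fit_values, dtype=float)
    uniq = np.unique(fit)
    if uniq.size <= max(2, bins):
        edges = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    else:
        qs = np.linspace(0, 1, bins + 1)[1:-1]
        edges = np.unique(np.quantile(fit, qs))
    codes = np.searchsorted(edges, values, side="right").astype(np.int64)
    return DiscretizedFeature(codes=codes, n_levels=len(edges) + 1, edges=edges)


def discretize_matrix(
    X: np.ndarray, bins: int = 5, fit_rows=None
) -> list[DiscretizedFeature]:
    """Discretize each column of ``X``; edges learned on ``fit_rows`` only."""
    X = np.asarray(X, dtype=float)
    fit = X if fit_rows is None else X[np.asarray(fit_rows, dtype=int)]
    return [discretize(X[:, j], bins=bins, fit_values=fit[:, j]) for j in range(X.shape[1])]


def _as_codes(v) -> tuple[np.ndarray, int]:
    if isinstance(v, DiscretizedFeature):
        return v.codes, v.n_levels
    codes = np.asarray(v, dtype=np.int64)
    return codes, int(codes.max()) + 1 if codes.size else 1


def entropy(v) -> float:
    """Plug-in Shannon entropy in bits."""
    codes, n = _as_codes(v)
    p = np.bincount(codes, minlength=n) / len(codes)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(q, r) -> float:
    """Plug-in mutual information in bits between two discrete variables."""
    qc, nq = _as_codes(q)
    rc, nr = _as_codes(r)
    if len(qc) != len(rc):
        raise ValueError("variables must have the same subject count")
    if len(qc) == 0:
        raise ValueError("need at least one subject")
    n = len(qc)
    joint = np.bincount(qc * nr + rc, minlength=nq * nr).reshape(nq, nr) / n
    pq = joint.sum(axis=1, keepdims=True)
    pr = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (pq @ pr)[mask]
    return float(max((joint[mask] * np.log2(ratio)).sum(), 0.0))


def joint_variable(a, b) -> DiscretizedFeature:
    """Product-alphabet joint variable of two discrete variables."""
    ac, na = _as_codes(a)
    bc, nb = _as_codes(b)
    return DiscretizedFeature(
        codes=ac * nb + bc, n_levels=na * nb, edges=np.empty(0)
    )


def jmi_score(candidate, selected: list, y) -> float:
    """JMI criterion value for adding ``candidate`` given ``selected``.

    Empty selected set: I(candidate; Y).  Otherwise the sum over selected
    features j of I(candidate, F_j; Y) on the product alphabet.
    """
    if not selected:
        return mutual_information(candidate, y)
    return float(
        sum(mutual_information(joint_variable(candidate, s), y) for s in selected)
    )


@dataclass
class SelectionResult:
    """Ordered selected feature indices with per-step criterion values."""

    selected: list[int]
    scores: list[float]
    n_requested: int


def jmi_select(
    X: np.ndarray,
    y: np.ndarray,
    n: int,
    bins: int = 5,
    fit_rows=None,
) -> SelectionResult:
    """Greedy forward JMI selection of ``n`` features from the columns of X.

    Step 1 picks argmax I(F;Y); step k picks argmax of the cumulative
    pairwise criterion.  Ties break to the lowest feature index.  The greedy
    trace is deterministic given the data.  ``n`` greater than the feature
    count is clamped with a warning.
    """
    X = np.asarray(X, dtype=float)
    P = X.shape[1]
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > P:
        warnings.warn(f"n={n} exceeds feature count {P}; clamped", stacklevel=2)
        n = P
    feats = discretize_matrix(X, bins=bins, fit_rows=fit_rows)
    yc, ny = _as_codes(np.asarray(y))
    # map labels to dense codes
    if yc.min() < 0 or ny > 2:
        _, yc = np.unique(yc, return_inverse=True)
        yc = yc.astype(np.int64)

    relevance = np.array([mutual_information(f, yc) for f in feats])
    remaining = list(range(P))
    cumulative = relevance.copy()  # step-1 criterion; later: sum of pair MIs
    selected: list[int] = []
    scores: list[float] = []

    first = int(np.argmax(relevance))
    selected.append(first)
    scores.append(float(relevance[first]))
    remaining.remove(first)
    cumulative = np.zeros(P)

    while len(selected) < n:
        last = feats[selected[-1]]
        for j in remaining:
            cumulative[j] += mutual_information(joint_variable(feats[j], last), yc)
        arr = np.full(P, -np.inf)
        arr[remaining] = cumulative[remaining]
        best = int(np.argmax(arr))  # argmax returns the lowest index on ties
        selected.append(best)
        scores.append(float(cumulative[best]))
        remaining.remove(best)

    return SelectionResult(selected=selected, scores=scores, n_requested=n)
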
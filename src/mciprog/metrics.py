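"""Goodness-of-fit metrics: rank-statistic AUC and confusion-matrix scores.

AUC is the Mann-Whitney probability that a random positive outscores a
random negative, computed from midranks so that tied scores contribute 1/2.
Confusion metrics are evaluated at a decision threshold (0 for margin
scores, 0.5-probability equivalently 0 log-odds for logistic scores); the
positive class is the progressor (+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["roc_auc", "compute_metrics", "MetricsSummary", "summarize_folds"]

METRIC_NAMES = ["auc", "sensitivity", "specificity", "accuracy", "precision", "recall", "f1"]


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve by the midrank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(scores: np.ndarray, y: np.ndarray, threshold: float = 0.0) -> dict:
    """AUC plus thresholded confusion-matrix metrics for one evaluation.

    Predicts positive when score >= threshold.  Precision is reported as 0
    when no positives are predicted; F1 is the harmonic mean of precision
    and recall (0 when their sum is 0).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pred = np.where(scores >= threshold, 1, -1)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "auc": roc_auc(scores, y),
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "precision": prec,
        "recall": sens,
        "f1": f1,
    }


@dataclass
class MetricsSummary:
    """Per-fold metrics with mean +/- sd aggregates."""

    per_fold: pd.DataFrame
    mean: dict
    sd: dict
    n_features: int | None = None
    training_fraction: float | None = None
    details: dict | None = None  # per-fold selections / chosen hyperparameters

    def __getitem__(self, metric: str) -> tuple[float, float]:
        return self.mean[metric], self.sd[metric]


def summarize_folds(
    rows: list[dict], n_features=None, training_fraction=None, details=None
) -> MetricsSummary:
    df = pd.DataFrame(rows)
    return MetricsSummary(
        per_fold=df,
        mean={m: float(df[m].mean()) for m in df.columns},
        sd={m: float(df[m].std(ddof=0)) for m in df.columns},
        n_features=n_features,
        training_fraction=training_fraction,
        details=details,
    )
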
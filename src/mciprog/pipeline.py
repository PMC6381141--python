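"""Nested stratified cross-validation, generalizability sweep and ablation.

The evaluation protocol: an outer stratified k-fold loop estimates
generalized performance; within each outer training set, features are
standardized and ranked by the JMI criterion, and hyperparameters are
chosen by an inner stratified CV grid search maximizing mean validation
AUC.  Every training-fold artifact (standardizer, feature ranking, chosen
hyperparameters) is a pure function of the training rows, so held-out rows
never leak into model selection.

On top of nested CV sit two study designs: a generalizability sweep that
re-runs the evaluation over a grid of feature-subset sizes and tracks
train/test AUC against the feature/training-sample ratio (flagging models
whose test AUC declines at high ratios as overfit-prone), and a modality
ablation that scores each modality block alone and then removes blocks in
descending order of solo AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureTable, standardize, stratified_kfold
from .glm import glm_decision, glm_fit, glm_path
from .infotheory import jmi_select
from .metrics import MetricsSummary, compute_metrics, roc_auc, summarize_folds
from .mkl import mkl_decision, mkl_fit
from .svm import KernelSpec, svm_decision, svm_fit

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "default_grid",
    "nested_cv",
    "generalizability_sweep",
    "GeneralizabilityCurve",
    "modality_ablation",
    "AblationReport",
]

MODEL_NAMES = ("svm-linear", "svm-rbf", "mkl-linear", "glm-elasticnet")


def default_grid(model: str, n_features: int | None = None, compact: bool = False) -> list[dict]:
    """Default hyperparameter grid for a model.

    SVM: box constraint C over 7 log-spaced decades (RBF adds a sigma grid
    scaled by sqrt(P)); GLM: lambda over 9 log-spaced values in [1e-4, 1]
    crossed with elasticity alpha in {0.1, ..., 1.0}; MKL: C = 1 (the
    simplex weights are optimized internally, not grid-searched).
    ``compact=True`` gives the reduced grids used by the sweep drivers
    (3 C values; alpha = 0.5 with 5 lambdas).
    """
    if model == "svm-linear":
        Cs = list(np.geomspace(1e-3, 10.0, 5)) if compact else list(np.geomspace(1e-3, 1e3, 7))
        return [{"C": float(c)} for c in Cs]
    if model == "svm-rbf":
        Cs = [0.1, 1.0, 10.0] if compact else list(np.geomspace(1e-3, 1e3, 7))
        scale = np.sqrt(n_features) if n_features else 1.0
        sigmas = [0.5, 1.0, 5.0] if compact else [0.1, 0.5, 1.0, 2.0, 5.0, 10.0]
        return [
            {"C": float(c), "sigma": float(s * scale)} for c in Cs for s in sigmas
        ]
    if model == "mkl-linear":
        return [{"C": 1.0}]
    if model == "glm-elasticnet":
        lams = np.geomspace(1e-4, 1.0, 5 if compact else 9)
        alphas = [0.5] if compact else [round(0.1 * i, 1) for i in range(1, 11)]
        return [{"lam": float(l), "alpha": float(a)} for a in alphas for l in lams]
    raise ValueError(f"unknown model {model!r}")


def _fit_scorer(model: str, params: dict, X: np.ndarray, y: np.ndarray):
    """Fit one model and return a decision-value scorer for new rows."""
    if model == "svm-linear":
        m = svm_fit(X, y, KernelSpec("linear"), C=params["C"])
        return lambda Xn: svm_decision(m, Xn)
    if model == "svm-rbf":
        m = svm_fit(X, y, KernelSpec("rbf", sigma=params["sigma"]), C=params["C"])
        return lambda Xn: svm_decision(m, Xn)
    if model == "mkl-linear":
        m = mkl_fit(X, y, C=params["C"], groups=params.get("groups"))
        return lambda Xn: mkl_decision(m, Xn)
    if model == "glm-elasticnet":
        m = glm_fit(X, (y == 1).astype(float), params["lam"], params["alpha"])
        return lambda Xn: glm_decision(m, Xn)  # log-odds; 0 <=> probability 0.5
    raise ValueError(f"unknown model {model!r}")


def _complexity_key(model: str, params: dict, index: int):
    """Tie-break order among equal-AUC combinations: least complex first.

    Smaller C (SVM/MKL), larger lambda (GLM), then original grid order.
    """
    if model in ("svm-linear", "svm-rbf", "mkl-linear"):
        return (params["C"], index)
    return (-params["lam"], index)


def _grid_search(
    model: str, grid: list[dict], X: np.ndarray, y: np.ndarray, inner_k: int, seed: int
) -> dict:
    """Inner stratified-CV grid search maximizing mean validation AUC."""
    if len(grid) == 1:
        return grid[0]
    plan = stratified_kfold(y, k=inner_k, seed=seed)
    mean_auc = np.zeros(len(grid))
    if model == "glm-elasticnet":
        # warm-started lambda paths per alpha: one pass per inner fold
        alphas: dict[float, list[int]] = {}
        for i, p in enumerate(grid):
            alphas.setdefault(p["alpha"], []).append(i)
        for tr, va in plan.folds:
            y01 = (y[tr] == 1).astype(float)
            for alpha, idxs in alphas.items():
                lams = np.array([grid[i]["lam"] for i in idxs])
                models = glm_path(X[tr], y01, lams, alpha=alpha)
                for i, m in zip(idxs, models):
                    scores = glm_decision(m, X[va])
                    mean_auc[i] += _safe_auc(scores, y[va]) / inner_k
    else:
        for tr, va in plan.folds:
            for i, params in enumerate(grid):
                scorer = _fit_scorer(model, params, X[tr], y[tr])
                mean_auc[i] += _safe_auc(scorer(X[va]), y[va]) / inner_k
    best = mean_auc.max()
    ties = [i for i in range(len(grid)) if mean_auc[i] >= best - 1e-12]
    chosen = min(ties, key=lambda i: _complexity_key(model, grid[i], i))
    return grid[chosen]


def _safe_auc(scores: np.ndarray, y: np.ndarray) -> float:
    return roc_auc(scores, y) if len(np.unique(y)) > 1 else 0.5


def nested_cv(
    table: FeatureTable,
    model: str,
    n_features: int | None = None,
    outer_k: int = 10,
    inner_k: int = 10,
    grid: list[dict] | None = None,
    seed: int = 0,
    bins: int = 5,
    feature_ranking: str = "jmi",
) -> MetricsSummary:
    """Nested stratified CV evaluation of one model.

    Per outer fold: standardize on training rows, select ``n_features`` by
    greedy JMI on training rows only (``feature_ranking="none"`` or
    ``n_features=None`` uses all columns), grid-search hyperparameters by
    inner stratified CV, refit on the full outer-training set, and score
    the outer-test set.  Returns per-fold and mean +/- sd metrics; the
    per-fold frame also carries the training-set AUC.
    """
    table.validate()
    if grid is None:
        grid = default_grid(model, n_features or table.n_features)
    plan = stratified_kfold(table.y, k=outer_k, seed=seed)
    rows = []
    details = {"selected": [], "params": []}
    for f, (tr, te) in enumerate(plan.folds):
        try:
            std, _ = standardize(table, reference=tr)
            X, y = std.X, std.y
            if n_features is not None and feature_ranking == "jmi":
                sel = jmi_select(X[tr], y[tr], n=n_features, bins=bins)
                cols = np.array(sel.selected, dtype=int)
            else:
                cols = np.arange(table.n_features)
            Xtr, Xte = X[np.ix_(tr, cols)], X[np.ix_(te, cols)]
            params = _grid_search(model, grid, Xtr, y[tr], inner_k, seed=seed + 101 * f)
            scorer = _fit_scorer(model, params, Xtr, y[tr])
            row = compute_metrics(scorer(Xte), y[te], threshold=0.0)
            row["train_auc"] = _safe_auc(scorer(Xtr), y[tr])
            rows.append(row)
            details["selected"].append([table.feature_names[c] for c in cols])
            details["params"].append(params)
            logger.info("fold %d: params=%s test_auc=%.3f", f, params, row["auc"])
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"nested CV failed in outer fold {f}") from exc
    return summarize_folds(
        rows,
        n_features=n_features or table.n_features,
        training_fraction=1.0 - 1.0 / outer_k,
        details=details,
    )


@dataclass
class GeneralizabilityCurve:
    """Train/test AUC as a function of the feature/training-sample ratio."""

    model: str
    n_features: list[int]
    ratios: list[float]  # n_features / n_training_samples, strictly increasing
    train_auc_mean: list[float]
    train_auc_sd: list[float]
    test_auc_mean: list[float]
    test_auc_sd: list[float]
    overfit_prone: bool
    slope_upper_half: float
    slope_se: float


def _upper_half_slope(ratios: np.ndarray, auc: np.ndarray) -> tuple[float, float]:
    """OLS slope and its standard error over the upper half of the ratios."""
    half = ratios >= np.median(ratios)
    x, z = ratios[half], auc[half]
    if len(x) < 3:
        return 0.0, np.inf
    xc = x - x.mean()
    slope = float((xc @ z) / (xc @ xc))
    resid = z - z.mean() - slope * xc
    se = float(np.sqrt((resid @ resid) / (len(x) - 2) / (xc @ xc)))
    return slope, se


def generalizability_sweep(
    table: FeatureTable,
    models: list[str],
    feature_grid: list[int],
    k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    grids: dict[str, list[dict]] | None = None,
    bins: int = 5,
) -> dict[str, GeneralizabilityCurve]:
    """Train/test AUC sweep over feature-subset sizes for several models.

    The JMI ranking is computed once per outer fold at the largest grid
    value and sliced to prefixes (the greedy trace is prefix-consistent),
    so every model sees identical feature subsets and folds.  A model is
    flagged overfit-prone when its test-AUC slope over the upper half of
    the ratio range is negative beyond its standard error.
    """
    table.validate()
    feature_grid = sorted(set(int(n) for n in feature_grid))
    if feature_grid[-1] > table.n_features:
        raise ValueError("feature grid exceeds feature count")
    if grids is None:
        grids = {m: default_grid(m, table.n_features, compact=True) for m in models}
    plan = stratified_kfold(table.y, k=k, seed=seed)
    n_train_mean = float(np.mean([len(tr) for tr, _ in plan.folds]))

    # test_auc[model][i_grid][fold], train likewise
    acc = {m: {"train": [], "test": []} for m in models}
    for m in models:
        for _ in feature_grid:
            acc[m]["train"].append([])
            acc[m]["test"].append([])

    for f, (tr, te) in enumerate(plan.folds):
        std, _ = standardize(table, reference=tr)
        X, y = std.X, std.y
        ranking = jmi_select(X[tr], y[tr], n=feature_grid[-1], bins=bins).selected
        for i, n in enumerate(feature_grid):
            cols = np.array(ranking[:n], dtype=int)
            Xtr, Xte = X[np.ix_(tr, cols)], X[np.ix_(te, cols)]
            for m in models:
                params = _grid_search(
                    m, grids[m], Xtr, y[tr], inner_k, seed=seed + 101 * f + 7 * i
                )
                scorer = _fit_scorer(m, params, Xtr, y[tr])
                acc[m]["train"][i].append(_safe_auc(scorer(Xtr), y[tr]))
                acc[m]["test"][i].append(_safe_auc(scorer(Xte), y[te]))

    ratios = np.array([n / n_train_mean for n in feature_grid])
    curves = {}
    for m in models:
        tr_arr = np.array(acc[m]["train"])  # grid x folds
        te_arr = np.array(acc[m]["test"])
        te_mean = te_arr.mean(axis=1)
        slope, se = _upper_half_slope(ratios, te_mean)
        curves[m] = GeneralizabilityCurve(
            model=m,
            n_features=list(feature_grid),
            ratios=[float(r) for r in ratios],
            train_auc_mean=[float(v) for v in tr_arr.mean(axis=1)],
            train_auc_sd=[float(v) for v in tr_arr.std(axis=1)],
            test_auc_mean=[float(v) for v in te_mean],
            test_auc_sd=[float(v) for v in te_arr.std(axis=1)],
            overfit_prone=bool(slope < 0 and slope < -se),
            slope_upper_half=slope,
            slope_se=se,
        )
    return curves


@dataclass
class AblationReport:
    """Solo-modality AUCs and the cumulative-removal curve."""

    solo: dict[str, tuple[float, float]]  # modality -> (auc mean, sd)
    removal_order: list[str]  # descending solo AUC; name order on ties
    cumulative: list[dict] = field(default_factory=list)
    # each entry: {"removed": modality, "auc_mean": ..., "auc_sd": ..., "n_features": ...}


def modality_ablation(
    table: FeatureTable,
    model: str = "svm-linear",
    k: int = 10,
    inner_k: int = 5,
    seed: int = 0,
    grid: list[dict] | None = None,
) -> AblationReport:
    """Per-modality predictive ability and iterative-removal curve.

    Solo runs use all features of one modality (no JMI step).  Modalities
    are then removed in descending order of solo AUC; after each removal
    the model is re-evaluated on every remaining feature.  Removing the
    final modality leaves no predictors, recorded as chance AUC 0.5.
    """
    table.validate()
    modalities = table.modalities()
    if len(modalities) < 2:
        raise ValueError("ablation needs at least 2 modalities")
    if grid is None:
        grid = default_grid(model, table.n_features, compact=True)

    solo: dict[str, tuple[float, float]] = {}
    for mod in modalities:
        idx = table.feature_indices(mod)
        if idx.size == 0:
            warnings.warn(f"modality {mod!r} has no features; skipped", stacklevel=2)
            continue
        summary = nested_cv(
            table.subset_features(idx), model, n_features=None,
            outer_k=k, inner_k=inner_k, grid=grid, seed=seed,
        )
        solo[mod] = (summary.mean["auc"], summary.sd["auc"])

    order = sorted(solo, key=lambda m: (-solo[m][0], m))
    cumulative = []
    remaining = [m for m in modalities if m in solo]
    for mod in order:
        remaining = [m for m in remaining if m != mod]
        idx = np.concatenate(
            [table.feature_indices(m) for m in remaining]
        ) if remaining else np.empty(0, dtype=int)
        if idx.size:
            summary = nested_cv(
                table.subset_features(np.sort(idx)), model, n_features=None,
                outer_k=k, inner_k=inner_k, grid=grid, seed=seed,
            )
            entry = {
                "removed": mod,
                "auc_mean": summary.mean["auc"],
                "auc_sd": summary.sd["auc"],
                "n_features": int(idx.size),
            }
        else:
            entry = {"removed": mod, "auc_mean": 0.5, "auc_sd": 0.0, "n_features": 0}
        cumulative.append(entry)
    return AblationReport(solo=solo, removal_order=order, cumulative=cumulative)
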
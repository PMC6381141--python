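"""Feature tables, standardization and stratified partitioning.

The in-memory container is a subjects x features matrix with {-1,+1}
progression labels (+1 = progressor) and a feature -> modality map.
Standardization is fit on a reference row subset (by default the training
rows of a fold, so test rows never leak into the learned statistics) and
stratified splits preserve per-class proportions to within one subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "Standardizer",
    "SplitPlan",
    "standardize",
    "stratified_split",
    "stratified_kfold",
    "read_feature_table",
    "write_feature_table",
    "StratificationError",
]


class StratificationError(ValueError):
    """Raised when labels cannot be partitioned as requested."""


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and modality assignments."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    modality_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def modalities(self) -> list[str]:
        """Distinct modalities in first-appearance order."""
        seen: dict[str, None] = {}
        for name in self.feature_names:
            seen.setdefault(self.modality_map.get(name, "unknown"))
        return list(seen)

    def feature_indices(self, modality: str) -> np.ndarray:
        return np.array(
            [
                i
                for i, name in enumerate(self.feature_names)
                if self.modality_map.get(name) == modality
            ],
            dtype=int,
        )

    def subset_features(self, indices) -> "FeatureTable":
        indices = np.asarray(indices, dtype=int)
        names = [self.feature_names[i] for i in indices]
        return FeatureTable(
            X=self.X[:, indices],
            y=self.y,
            feature_names=names,
            modality_map={n: self.modality_map.get(n, "unknown") for n in names},
        )

    def validate(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN or Inf")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal feature count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must lie in {-1, +1}")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")


@dataclass
class Standardizer:
    """Per-feature centering/scaling statistics learned from reference rows.

    Population standard deviation (divide by N) by default; ``ddof=1`` gives
    the sample convention.  Constant features get sd = 1 with a warning so
    the transform stays finite.
    """

    mean_: np.ndarray
    sd_: np.ndarray
    ddof: int = 0

    @classmethod
    def fit(cls, X: np.ndarray, rows=None, ddof: int = 0) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        ref = X if rows is None else X[np.asarray(rows, dtype=int)]
        if ref.shape[0] == 0:
            raise ValueError("reference row set must be non-empty")
        mean = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=ddof) if ref.shape[0] > ddof else np.zeros(X.shape[1])
        constant = sd == 0
        if np.any(constant):
            warnings.warn(
                f"{int(constant.sum())} constant feature(s) in reference rows; "
                "sd set to 1",
                stacklevel=2,
            )
            sd = np.where(constant, 1.0, sd)
        return cls(mean_=mean, sd_=sd, ddof=ddof)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_


@dataclass
class SplitPlan:
    """Seeded stratified fold assignments."""

    folds: list[tuple[np.ndarray, np.ndarray]]  # (train indices, test indices)
    n_folds: int
    seed: int


def standardize(
    table: FeatureTable, reference=None, ddof: int = 0
) -> tuple[FeatureTable, Standardizer]:
    """Standardize features using statistics from the reference rows only.

    ``reference=None`` uses all rows (the global, fit-on-everything
    convention); passing the training indices of a fold gives the
    leakage-safe variant where held-out rows are transformed with training
    statistics.
    """
    scaler = Standardizer.fit(table.X, rows=reference, ddof=ddof)
    out = FeatureTable(
        X=scaler.transform(table.X),
        y=table.y,
        feature_names=list(table.feature_names),
        modality_map=dict(table.modality_map),
    )
    return out, scaler


def _class_indices(y: np.ndarray) -> dict[int, np.ndarray]:
    y = np.asarray(y)
    return {int(c): np.flatnonzero(y == c) for c in np.unique(y)}


def stratified_split(
    y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test split.

    Per class, floor(class_size * test_fraction) subjects go to the test
    set (remainder to training), chosen uniformly at random under ``seed``.
    """
    y = np.asarray(y)
    if not (0.0 < test_fraction < 1.0):
        raise StratificationError(
            f"test_fraction must lie in (0, 1), got {test_fraction}"
        )
    classes = _class_indices(y)
    if any(len(idx) < 2 for idx in classes.values()):
        raise StratificationError("every class needs at least 2 members")
    rng = np.random.default_rng(seed)
    test_parts = []
    for c in sorted(classes):
        idx = classes[c]
        n_test = int(np.floor(len(idx) * test_fraction))
        if n_test == 0:
            raise StratificationError(
                f"test_fraction {test_fraction} gives an empty test set for class {c}"
            )
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def stratified_kfold(y: np.ndarray, k: int, seed: int) -> SplitPlan:
    """Stratified k-fold partition: within-class permutation, then chunking.

    Every subject appears in exactly one test fold; per-fold class counts
    differ from the even split by at most one subject.
    """
    y = np.asarray(y)
    if k < 2:
        raise StratificationError("k must be at least 2")
    classes = _class_indices(y)
    if any(len(idx) < k for idx in classes.values()):
        raise StratificationError(f"every class needs at least k={k} members")
    rng = np.random.default_rng(seed)
    chunks_per_class = {
        c: np.array_split(rng.permutation(idx), k) for c, idx in sorted(classes.items())
    }
    folds = []
    everything = np.arange(len(y))
    for i in range(k):
        test = np.sort(np.concatenate([chunks_per_class[c][i] for c in chunks_per_class]))
        train = np.setdiff1d(everything, test)
        folds.append((train, test))
    return SplitPlan(folds=folds, n_folds=k, seed=seed)


def read_feature_table(
    features_csv, labels_csv=None, modality_json=None
) -> FeatureTable:
    """Read a feature table from plain-text files.

    ``features_csv``: header row of feature names, one row per subject.
    ``labels_csv``: two columns (subject_id, label in {-1,+1}).
    ``modality_json``: {feature_name: modality}.
    """
    df = pd.read_csv(features_csv)
    y = (
        pd.read_csv(labels_csv)["label"].to_numpy()
        if labels_csv is not None
        else np.ones(len(df), dtype=int)
    )
    modality_map = (
        json.loads(Path(modality_json).read_text()) if modality_json else {}
    )
    table = FeatureTable(
        X=df.to_numpy(dtype=float),
        y=y,
        feature_names=list(df.columns),
        modality_map=modality_map,
    )
    return table


def write_feature_table(
    table: FeatureTable, features_csv, labels_csv=None, modality_json=None
) -> None:
    pd.DataFrame(table.X, columns=table.feature_names).to_csv(features_csv, index=False)
    if labels_csv is not None:
        pd.DataFrame(
            {"subject_id": np.arange(table.n_subjects), "label": table.y}
        ).to_csv(labels_csv, index=False)
    if modality_json is not None:
        Path(modality_json).write_text(json.dumps(table.modality_map, indent=1))
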
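"""Cross-validated goodness-of-fit metrics for the three linear classifiers.

Nested stratified CV (JMI feature selection and hyperparameter grid search
on training folds only) with each model's most generalizable feature-count:
MKL 5, linear SVM 65, elastic-net GLM 25.  Writes a metrics table with one
row per model.
"""

import argparse
from pathlib import Path

import pandas as pd

from mciprog import default_adni_like_spec, default_grid, generate_cohort, nested_cv

CONFIG = [
    ("mkl-linear", 5, None),
    ("svm-linear", 65, None),
    ("glm-elasticnet", 25, "compact"),
]
METRICS = ["auc", "sensitivity", "specificity", "accuracy", "precision", "recall", "f1"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outer-k", type=int, default=10)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = generate_cohort(default_adni_like_spec(seed=args.seed)).as_table()
    rows = []
    for model, n_features, gridmode in CONFIG:
        grid = default_grid(model, n_features, compact=True) if gridmode else None
        inner_k = 5 if gridmode else 10
        s = nested_cv(
            table, model, n_features=n_features,
            outer_k=args.outer_k, inner_k=inner_k, grid=grid, seed=args.seed,
        )
        row = {"model": model, "n_features": n_features,
               "training_size": f"{100 * s.training_fraction:.0f}%"}
        for metric in METRICS:
            row[metric] = f"{s.mean[metric]:.2f}({s.sd[metric]:.2f})"
        rows.append(row)
        print(f"{model:16s} n={n_features:3d} test AUC "
              f"{s.mean['auc']:.3f} +/- {s.sd['auc']:.3f}")
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "prediction_performance.csv", index=False)
    print(df.to_string(index=False))
    print(f"written to {args.outdir}/prediction_performance.csv")


if __name__ == "__main__":
    main()
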
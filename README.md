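# mciprog

Machine-learning pipeline for predicting short-term progression from mild
cognitive impairment (MCI) to Alzheimer's disease (AD) dementia from
multimodal tabular biomarkers — CSF assays, amyloid- and FDG-PET, structural
MRI, cognitive scores, cognitive-resilience surrogates, genetics and
demographics.

It is written for biostatisticians and ML researchers who want a tested,
leakage-safe reference implementation of this class of clinical prediction
study: information-theoretic feature selection, linear and nonlinear
classifiers, a linear-separability diagnostic, generalizability analysis,
modality ablation and sparse minimal-predictor extraction — all exercised
end-to-end on a synthetic cohort generator that emulates the structure of a
135-subject, 94-feature multimodal MCI cohort (39 progressors within three
years, 96 non-progressors), since the archives hosting such clinical data are
access-restricted.

## Methods at a glance

- **JMI feature selection.** Mutual information
  I(Q;R) = Σ_{q,r} p(q,r) log₂ p(q,r)/(p(q)p(r)) is estimated by the plug-in
  rule on equal-frequency-discretized features; greedy forward selection adds
  the candidate F maximizing Σ_{j∈selected} I(F, F_j; Y) — the joint-mutual-
  information criterion, which prefers features that are informative and
  non-redundant.
- **Classifiers.** Soft-margin SVM via the boxed dual
  max_α Σα_i − ½ΣΣ α_iα_j Y_iY_j K(X_i,X_j), s.t. Σα_iY_i = 0, 0 ≤ α_i ≤ C,
  with linear and RBF kernels; multiple kernel learning (MKL) replacing K by
  Σ_m β_m K_m with per-feature linear kernels and simplex weights
  (β_m ≥ 0, Σβ_m = 1); and logistic regression with the elastic-net penalty
  λ[(1−α)/2‖β‖₂² + α‖β‖₁] solved by coordinate descent (α = 1 is the LASSO).
- **Evaluation.** Nested stratified cross-validation: standardization, JMI
  ranking and hyperparameter grid search (maximizing inner-CV AUC) are fitted
  on training folds only; outer folds report AUC, sensitivity, specificity,
  accuracy, precision, recall and F1 (positive class = progressor).
- **Linear-separability test.** Sigmoid-transformed SVM projections
  (histogram-of-projections method, Platt-calibrated so linear and RBF
  profiles share the [0,1] scale): near-identical probability profiles under
  the two kernels (Pearson ρ ≥ 0.95, error gap ≤ 0.02) mean a linear decision
  boundary suffices.
- **Generalizability.** Train/test AUC tracked against the ratio
  (#features used) / (#training samples); a model whose test AUC declines at
  high ratios is flagged overfit-prone. Per-feature MKL, which optimizes
  roughly twice as many parameters as a plain SVM, shows this signature.

## Worked example

```
$ python analysis/02_linear_separability.py --seed 1
default cohort: rho=0.9714, errors 11.11% (linear) vs 11.11% (RBF) -> linearly-separable
xor cohort:     rho=0.0458, errors 46.50% (linear) vs 10.50% (RBF) -> not-linearly-separable
```

On the default (linear-geometry) cohort the linear- and RBF-kernel SVMs
produce nearly identical held-out probability profiles (ρ = 0.97) and equal
misclassification errors, so the data are linearly separable and linear
classifiers suffice. On the xor-geometry control — where the label is the
sign of a product of two latents, which no hyperplane can capture — the RBF
kernel cuts the error from 46.5% to 10.5% and the verdict flips.

```
$ python analysis/04_prediction_performance.py --seed 1
mkl-linear       n=  5 test AUC 0.891 +/- 0.073
svm-linear       n= 65 test AUC 0.929 +/- 0.058
glm-elasticnet   n= 25 test AUC 0.930 +/- 0.060
```

Ten-fold nested CV at each model's most generalizable feature count: the
linear SVM and elastic-net GLM reach test AUC ≈ 0.93 on the synthetic
cohort's operating regime, with MKL close behind at its small feature budget.

```
$ python analysis/06_minimal_predictors.py --seed 1
LASSO minimal set: 5 features, outer-CV AUC 0.882 +/- 0.061
  CSF            CSF_1, CSF_2, CSF_3
  FDGPET         FDGPET_3
  SMRI           SMRI_1
```

The LASSO (λ by the one-standard-error rule) compresses 94 correlated
features into 5 predictors — the three CSF markers plus one FDG-PET and one
SMRI feature — while keeping a cross-validated AUC of 0.88.

The numbered scripts under `analysis/` run the full study in order:
cohort simulation, separability, generalizability sweep, prediction
performance, modality ablation, minimal predictors. Each writes its tables
under `results/`.

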
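# Methods

This note documents the models, the synthetic cohort generator, the
numerical choices and the known limitations of the package. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## The prediction problem

Given a subjects × features table of baseline multimodal measurements and a
binary outcome (+1 = progression from MCI to AD dementia within three
years, −1 = no progression), the pipeline estimates how well, and how
robustly, the outcome can be predicted, and which measurements carry
independent information. The real cohorts this emulates are small
(N ≈ 135) and wide (P ≈ 94), with a ~29% positive rate and strong
cross-modality correlation — the regime where overfitting and information
leakage dominate naive analyses, and which every design choice below
addresses.

## Synthetic cohort generator

The generator (`mciprog.cohort`) is a latent-severity factor model:

- A disease-severity latent z ~ N(0,1) per subject drives the label through
  P(Y=+1 | z) = σ(a·z + c). The intercept c is solved by bisection (Gauss–
  Hermite quadrature for the expectation) so that E[prevalence] matches the
  target; the Bernoulli draw is then conditioned on its count by flipping
  the least-confident labels, so the realized positive count equals
  round(prevalence·n) exactly. The flips preserve the monotone dependence
  of the label on z.
- Each feature of a modality block with signal s is
  s·decay^j·z + redundancy·u + noise, where u ~ N(0,1) is a second shared
  latent inducing label-independent cross-modality correlation
  (redundancy default 0.3 — a free parameter with no empirical anchor) and
  j indexes features within the block.
- The within-block geometric decay (default 0.8) makes a minority of
  columns carry most of a modality's signal, as in real ROI or gene panels
  where only a few of many measures are disease-sensitive. The CSF block is
  the exception (decay 1.0): a 3-assay panel of amyloid-beta, total tau and
  phosphorylated tau has no tapering tail — each marker is individually
  strong. This is also what makes CSF the top solo modality.
- One genetics feature (APOE carrier status) and one demographics feature
  (gender) are binarized by thresholding the latent-normal value at zero,
  keeping a single generation mechanism.

The default specification mirrors the emulated study: 135 subjects,
prevalence 39/135, blocks CSF(3), amyloid-PET(4), FDG-PET(3), SMRI(69),
cognition(1), resilience(2), genetics(10), demographics(2) — 94 features —
with signal ordering CSF > amyloid-PET > FDG-PET > SMRI > genetics >
cognition > resilience > demographics. The global effect scale a = 4.0 was
calibrated once, by simulation, so that the reference pipeline (linear SVM,
65 JMI-selected features, 10-fold outer CV) operates at a mean test AUC
near 0.89 — the high-0.8/low-0.9 regime of published MCI-progression
classifiers — and then frozen.

The **xor geometry** replaces z by two latents z1, z2 with label
sign(z1·z2) (plus flip noise) and features loading on one latent each. No
linear combination of features separates the classes, while an RBF
classifier recovers the quadrant structure; this is the ground-truth
nonlinear control for the separability diagnostic.

What the generator does **not** emulate: missingness (complete-case data
by design), longitudinal trajectories, non-Gaussian marginals and outliers,
site/batch effects, and genuinely nonlinear biomarker–outcome relations in
the linear geometry. Passing tests therefore demonstrate correctness of
the machinery and its behavior under a plausible covariance/label
structure, not clinical performance on real cohorts.

## Feature selection

Mutual information is the plug-in estimate on discretized features
(equal-frequency bins, default B = 5, edges learned on training rows only;
features with ≤ B distinct values keep one code per level; 0·log 0 ≡ 0;
base-2 logs). Greedy JMI selection scores a candidate F by
Σ_{j∈selected} I(F, F_j; Y) over product alphabets — the standard pairwise
JMI criterion. The full k-variable joint MI is exponential in k and
unestimable at N = 135, which is why published JMI selectors compute the
pairwise form. Ties break to the lowest feature index, making the greedy
trace deterministic; the trace is prefix-consistent, so a ranking computed
once per fold serves every feature-budget in a sweep.

## Classifiers

**SVM.** The boxed dual is solved by SMO (scikit-learn's SVC); the module
surface exposes the full dual vector, intercept and support set, and
computes decisions through the representer form. Solver tolerance defaults
to 1e-3 (the libsvm convention) — tightening it to 1e-7 makes SMO crawl on
label-noise data without changing any decision meaningfully; the oracle
tests use 1e-8 on 15-point fixtures. RBF kernel convention:
K = exp(−‖x−x′‖²/(2σ²)). Degenerate precomputed kernels receive a 1e-10
diagonal jitter.

**MKL.** One linear kernel per feature (a per-modality grouping is
available via `groups=`). Alternating optimization: an SVM solve at fixed
simplex weights, then a multiplicative weight update
β_m ∝ β_m·S_m with S_m = (αy)ᵀK_m(αy), damped by backtracking so the
combined dual objective is non-increasing (this is the reduced-gradient
direction for minimizing the dual optimum over the simplex). Stopping:
relative objective change < 1e-4 or 200 iterations (best iterate returned
with a warning on non-convergence).

**Elastic-net GLM.** Penalized average negative log-likelihood with
unpenalized intercept, minimized by IRLS with coordinate-descent inner
sweeps (soft-thresholding, active-set iteration, numba-compiled kernel),
started from zero and damped so the true objective is monotone
non-increasing. Working weights are floored at 1e-5; outer stopping at
relative objective change ≤ 1e-7. At α = 1 and λ ≥ λ_max the solution is
exactly β = 0, β₀ = logit(prevalence). Warm-started λ paths make
grid searches cheap. SVM/MKL use {−1,+1} labels, the GLM {0,1}; the
converters are total.

**LASSO minimal set.** α = 1 with λ chosen by the one-standard-error rule
on inner-CV AUC (largest λ within one SE of the best): the AUC-vs-λ curve
is flat over a wide range, so the max-AUC λ keeps many redundant features,
while the 1-SE λ yields the sparse set the procedure exists to find. Outer
CV reports the generalized AUC of the whole procedure; the reported feature
set comes from a final all-rows fit, grouped by modality.

## Evaluation pipeline

Nested stratified CV: within each outer fold the standardizer (population
SD; sample SD configurable), the JMI ranking and the hyperparameter choice
are pure functions of the training rows — a perturbation test asserts
bit-identical artifacts when held-out rows change. Stratified partitioning
uses per-class permutation followed by chunking; per-class test counts
follow the floor rule with remainders to training. Default grids:
C ∈ 10^{−3..3} (7 values), σ ∈ {0.1,0.5,1,2,5,10}·√P, λ ∈ 10^{−4..0}
(9 values), α ∈ {0.1,…,1.0}; grid-search ties break to the least complex
combination (smallest C, largest λ, then grid order). Compact grids
(5 C values capped at 10, since C ≥ 100 is never selected at P ≈ 94 but
dominates SMO runtime; α = 0.5 with a 5-point λ path) serve the sweep
drivers. Confusion metrics use decision threshold 0 (probability 0.5 for
the GLM); AUC is the midrank Mann–Whitney statistic, cross-checked against
trapezoidal ROC integration. Note that under class imbalance a heavily
regularized SVM chosen by AUC can predict few positives at threshold 0, so
threshold-dependent metrics can be poor while AUC is high; AUC is the
headline metric throughout, as in the study design this implements.

**Generalizability sweep.** For feature budgets n over a grid, train and
test AUC are recorded against n / (mean training-fold size); the default
study grid is {5,15,30,45,60,75,94} with 5-fold outer CV (problem sizes
chosen so a full three-model sweep runs in seconds). A model is flagged
overfit-prone when the OLS slope of its test-AUC curve over the upper half
of the ratio range is negative beyond its standard error.

**Modality ablation.** Solo runs use all features of one block (no JMI
step), then blocks are removed in descending solo-AUC order with
re-evaluation on the remainder; removing the final block is recorded as
chance AUC 0.5. With high redundancy (shared-latent loading 0.8), removing
the top block costs little — the overlapping-information signature.

## Separability diagnostic

`separability_test` implements the single-fold contract: train linear- and
RBF-kernel SVMs (σ by inner CV), map test decision values d through a
sigmoid to probabilities, build per-class histograms on [0,1] (default 20
bins), find the error-minimizing probability threshold (midpoint
candidates, ties to the lower cut) and correlate the paired probabilities.
The default sigmoid is Platt calibration — a logistic fit of labels on the
training decision values with Platt's smoothed targets (N₊+1)/(N₊+2) and
1/(N₋+2) — because the raw unit-slope sigmoid does not remove kernel-scale
differences, which is the whole point of the transformation; the unit-slope
variant remains available (`calibration="identity"`) and a test asserts its
scale sensitivity.

`separability_study` is the study-level version: probabilities are pooled
over a stratified k-fold (default k = 10) so every subject contributes one
held-out probability per kernel and the error granularity is 1/N, and
per-kernel hyperparameters (C for linear; C and σ for RBF) are chosen by
inner CV with the one-standard-error, least-complex preference (largest σ,
smallest C) — without it, a spuriously sharp small-σ kernel occasionally
wins by a hair and degrades the comparison.

Verdict thresholds: linearly-separable iff ρ ≥ 0.95 and error gap ≤ 0.02;
not-linearly-separable iff the RBF error undercuts the linear error by
≥ 0.10; otherwise inconclusive. The thresholds are printed in every report.
On matched strong-signal cohort pairs (n = 400, linear vs xor geometry) the
diagnostic discriminates essentially perfectly. On the weak-signal default
cohort (N = 135) the achievable ρ distributes over ≈ 0.89–1.00, so a
fraction of runs lands "inconclusive" — the diagnostic's honest resolution
limit at this sample size; it never mislabels the linear construction as
nonlinear, and a unit test pins that.

## Known limitations

- The generator's single-latent linear geometry makes all informative
  features positively correlated through z; real cohorts have richer
  correlation structure (the redundancy latent u only partially emulates
  this).
- MI estimation is plug-in on 5-bin discretizations: biased upward for
  small N, adequate for ranking, not for absolute MI values.
- The MKL weight update is a monotone heuristic, verified against a coarse
  simplex grid oracle at small P; it is not a certified global optimizer.
- Threshold-0 confusion metrics can be degenerate for heavily regularized
  SVMs under class imbalance (see above).
- The separability verdict is a heuristic comparison with documented
  thresholds, not an inferential test.
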
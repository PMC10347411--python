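# Methods

## Overview

`brainage` estimates a subject's age from resting-state functional
connectivity (FC) and uses the discrepancy between estimated and
chronological age — the brain age gap (BAG) — as a marker of accelerated
functional aging. The pipeline is

1. **Connectivity** — Pearson correlation between every pair of regional
   time series (116-region AAL-style parcellation by default), giving a
   symmetric R x R matrix with unit diagonal per subject. Time-series length
   may differ across subjects; the correlation matrix is comparable
   regardless.
2. **Harmonization** — parametric empirical-Bayes ComBat on the flattened
   upper-triangle edge vectors (R(R-1)/2 = 6,670 features at R = 116),
   removing per-site location and scale effects while protecting age (and
   sex when present) as covariates.
3. **Graphs** — each region is a vertex whose feature vector is its full FC
   profile (row of the matrix, self-correlation included); directed edges
   (i, j) and (j, i) are kept where |r_ij| >= tau and carry the signed r_ij
   as a scalar edge feature. tau = 0 (the complete graph) is the default; a
   signed-threshold mode (r >= tau) is available by flag.
4. **Regressor** — a transformer-convolution graph network: per-layer, each
   vertex attends over its in-neighbors with scaled dot-product query/key/
   value attention, the scalar edge feature entering both key and value
   paths through a shared linear edge map, plus a skip (root) term. Each
   block is conv -> LayerNorm -> LeakyReLU; two blocks by default, then a
   channelwise mean readout over vertices and an MLP head
   (Linear -> ReLU -> BatchNorm -> Linear) with 32 hidden units and one
   output.
5. **Evaluation** — 10-fold cross-validation on controls with MSE loss,
   Adam (lr 1e-3, weight decay 1e-3, batch 16) and cosine annealing;
   MAE / RMSE / Pearson correlation (PCC) reported as mean +- SD across
   folds. Each diagnostic group is scored by all ten fold models; BAG =
   predicted - chronological age, averaged within group, mean +- SD across
   fold models.
6. **Explanation** — a GNNExplainer-style soft mask M = sigmoid(L) on the
   R x R vertex-feature table, optimized (100 Adam steps, lr 0.01) to keep
   the frozen model's prediction on the masked graph close to its original
   prediction, with sparsity penalty lambda * mean(M), lambda = 0.005.
   Region weight = row mean of the mask; group rankings average weights
   across subjects, ties broken by region index. Top-30% sets (35 regions
   of 116, round-half-up) are intersected across groups for shared/distinct
   regions.

## Numerical implementation of the regressor

The network, its gradients, Adam, and the mask optimization run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`brainage.autodiff`). Graphs over a common vertex set are processed
densely: vertex features as (batch, R, R), scalar edge features and the
adjacency as (batch, R, R), attention as a masked softmax over the last
axis. Because the edge feature is a scalar, its key/value contribution
factorizes and never materializes an (R, R, channels) tensor. Correctness
is established in the test suite against unvectorized straight-loop
implementations of the conv and the full forward pass, and against finite
differences for every primitive.

Details that matter:

- **Output affine.** The final linear layer's output is passed through a
  fixed (non-trained) affine y = scale * z + loc, with loc/scale set to the
  training fold's age mean/SD. Adam's per-parameter step size is scale-free,
  so without this the output head would need thousands of steps just to
  traverse the ~46-year age range; with it, the head works on an O(1) scale.
  This is ordinary target standardization folded into the model so that
  checkpoints are self-contained.
- **Isolated vertices** (possible at high thresholds) receive only the skip
  term; their attention row is exactly zero.
- **LayerNorm** uses eps = 1e-5 in the denominator and never divides by
  zero; BatchNorm uses batch statistics (differentiated through) during
  training and running averages at inference, so predictions are
  per-subject deterministic.
- **Initialization** is uniform fan-in scaling from one seeded generator;
  fold f uses model seed (base seed + f). Everything downstream of a seed
  is bit-reproducible.
- **Schedule**: lr(t) = lr_min + (lr - lr_min)(1 + cos(pi t/(T-1)))/2 over
  T epochs, lr_min = 1e-5.

## ComBat estimator

Per feature f, site i, subject j: y = alpha_f + x' beta_f + gamma_if +
delta_if * eps. Site intercepts and covariate effects are fit jointly by
least squares (no global intercept; the grand mean is the sample-size
weighted average of site intercepts, which makes site locations identifiable
as contrasts — the weighted per-feature sum of the location estimates is 0).
Data are standardized by the grand mean + covariate fit and the pooled
residual SD; per-site location/scale estimates are shrunk toward
moment-matched parametric priors (normal for locations, inverse-gamma for
squared scales) by iterating the conditional posterior means to an absolute
change below 1e-6 (at most 100 iterations). With a single feature the
across-feature priors are undefined and no shrinkage is applied, which
reduces to exact per-site mean/variance alignment. Constant features are
passed through with a warning. Unseen site labels at apply time are an
error, not a fallback.

Harmonization operates on the edge-vector table, then matrices are rebuilt
(clipped into (-0.999999, 0.999999), diagonal restored to 1). ComBat is fit
once on the full cohort before modeling; age is always protected.

## Synthetic study conditions

Real multi-site rs-fMRI cohorts of this kind are access-controlled, so the
package ships a generator that emulates their statistical shape and gives
every stage a planted ground truth. Defaults: R = 116 regions, 8 sites
(balanced round-robin assignment, >= 3 subjects per site), ages uniform on
[51, 97], six diagnostic groups (HC, SMC, EMCI, MCI, LMCI, AD) with planted
brain-age offsets Delta = 0, 1, 2, 3, 4, 5 years; the default cohort has
400 controls and 40 subjects per patient group. The latent brain age is
age + Delta + N(0, 1) jitter and is recorded only in provenance files.

Connectivity targets are built on the Fisher-z scale: a low-rank factor
baseline (5 factors, diagonal boosted to keep off-diagonal correlations
modest), plus beta1 * zscore(brain_age) on 60 randomly chosen signal edges
with slopes uniform on [0.2, 0.4] z-units per standardized year, plus
additive per-site shifts gamma_s ~ N(0, 0.1) and a multiplicative per-site
inflation delta_s = exp(N(0, 0.1)) of the subject-level iid edge noise
(SD 0.03) — exactly the location/scale structure ComBat assumes. The result
is mapped through tanh and projected to the nearest valid correlation matrix
(eigenvalues clipped at 1e-6, diagonal renormalized). Time series are white
noise colored by a symmetric square root of the target, with per-subject
lengths uniform on [120, 200].

Two calibration notes. First, iid edge noise makes a 116 x 116 matrix
decisively non-positive-definite (a symmetric perturbation with entry SD
sigma shifts the spectrum by about 2 sigma sqrt(R)), so the projection step
is always active and *shrinks the planted age signal*: measured
transmission of a planted brain-age offset through the projection is ~0.66
at noise SD 0.1, ~0.88 at 0.05 and ~0.97 at 0.03. The default of 0.03 keeps
the planted signal strong and recoverable — the condition the default
cohort is meant to represent — while realistic subject-level variability is
still present through finite-length estimation noise (~0.08 z-units per
edge at T ~ 150), which is PSD-consistent and therefore undistorted.
Second, the generator's site effects act on the Fisher-z scale while
harmonization operates on raw correlations; at the magnitudes used the
tanh is near-linear and ComBat removes the planted effects essentially
completely (at the default conditions the median site F statistic across
edges drops from ~2.7 to ~0.3; stronger planted site effects collapse the
same way).

What the generator does **not** emulate: hemodynamics or scanner physics,
autocorrelated BOLD noise, head motion, unbalanced site sizes, group
differences in age distribution or sex ratio, and any nonlinear age
effects. Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it models, not that it would reach any particular
accuracy on real scans.

## Cross-validation and problem sizes

Folds are a seeded random partition with sizes differing by at most one;
fold test sets partition the controls, and a SHA-256 fingerprint of each
test set is recorded so baseline comparisons can be audited to use the
identical partition. Baseline regressors on the flattened 6,670-feature
vectors: SVR, Gaussian-process regression, random forest, LASSO (inner-CV
regularization path), a deep fully-connected network with staged widths
(a 1-D adaptation of the AlexNet-style architecture, which as a 2-D
convolutional design does not apply to edge vectors), and an autoencoder
(reconstruction-pretrained encoder with a ridge head). Library defaults are
used where the method leaves choices open.

The default training length in `TrainingConfig` is 150 epochs. The shipped
acceptance script and the heavy end-to-end tests use 50 epochs on the
400-control cohort — at that depth the cross-validated slope of predicted
on true age has plateaued (~0.9) and further epochs change MAE by well
under the fold-to-fold SD; it is the package's chosen desk-scale operating
point. Group explanation uses the ensemble-mean prediction of all ten fold
models; the batched cohort explainer sums per-subject losses, which leaves
each subject's mask trajectory identical to subject-by-subject optimization
(verified in tests).

## Known limitations

- No regression-to-the-mean correction of BAG (none is applied upstream
  either); with a cross-validated slope below 1, group BAG estimates are
  mildly attenuated relative to the planted offsets.
- ComBat here is the linear-covariate parametric variant; no spline age
  model, no nonparametric priors, no longitudinal harmonization.
- The mask explainer learns vertex-feature masks only (no edge masks,
  no gradient/saliency methods, no model-level explanations).
- Tabular baselines and the GNN share fold partitions but not
  hyperparameter budgets; the comparison is protocol-matched, not
  budget-matched.
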
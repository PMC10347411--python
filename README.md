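# brainage

Brain-age prediction from resting-state functional connectivity with an
attention-based graph neural network, for researchers studying accelerated
functional aging in Alzheimer's disease and related conditions.

## The problem

A brain's functional connectome carries an age signal: correlations between
regional rs-fMRI time series drift systematically over the lifespan. A model
trained to predict chronological age from connectivity in healthy controls
defines a normative aging trajectory; applying it to patients yields the
**brain age gap**

    BAG = predicted age − chronological age,

whose elevation marks accelerated functional aging and is a candidate
biomarker for early Alzheimer's disease.

This package implements that analysis end to end:

- **Pearson functional connectivity** from per-subject T × R regional time
  series (R = 116 by default), robust to differing T across subjects.
- **ComBat harmonization** (parametric empirical Bayes) of the flattened
  6,670-edge vectors across acquisition sites, protecting age and sex.
- **Graph construction**: regions as vertices, FC rows as vertex features,
  |r| ≥ τ thresholded edges carrying the signed correlation (τ = 0 gives
  the complete graph).
- **Transformer-convolution regressor**: per vertex i with neighbors j,

      α_ij = softmax_j( q_i·k_ij / √d ),  q_i = W_q x_i,
      k_ij = W_k x_j + W_e e_ij,          v_ij = W_v x_j + W_e e_ij,
      out_i = Σ_j α_ij v_ij + W_r x_i,

  stacked twice with LayerNorm + LeakyReLU, mean readout, and a
  Linear→ReLU→BatchNorm→Linear head (32 hidden units, one output). Trained
  with MSE loss, Adam (lr 10⁻³, weight decay 10⁻³, batch 16), cosine
  annealing, 10-fold cross-validation on controls; reported as MAE / RMSE /
  PCC, mean ± SD over folds. Six tabular baselines (SVR, GPR, random
  forest, LASSO, a deep fully-connected network, an autoencoder) run on the
  identical fold partitions.
- **Perturbation explainability** (GNNExplainer-style): a soft mask on the
  vertex-feature table optimized to preserve the frozen model's prediction,
  giving per-region importance weights, group rankings, and top-30% shared/
  distinct region sets.
- **Synthetic cohorts**: a first-class generator of multi-site cohorts with
  planted age signal, site effects, and group-wise brain-age offsets, so
  every stage can be validated against known ground truth.

The network, its gradients, and the optimizers run on a compact
reverse-mode autodiff engine over numpy included in the package; see
`docs/methods.md` for the model, estimator, and generator details.

## Worked example

```python
from brainage import (
    CohortSpec, GroupSpec, ModelConfig, TrainingConfig,
    build_graph, cross_validate, evaluate_group, harmonize_matrices,
    pearson_fc, generate_cohort,
)

spec = CohortSpec(
    groups=(GroupSpec("HC", 0.0, 60), GroupSpec("AD", 5.0, 20)),
    n_regions=16, n_sites=4, n_signal_edges=10, seed=7,
)
cohort = generate_cohort(spec)                      # time series + phenotypes
fcs = [pearson_fc(ts) for ts in cohort.timeseries]  # 16x16 matrices
harmonized, _ = harmonize_matrices(fcs, cohort.phenotypes())

info = cohort.phenotypes().set_index("subject_id")
graphs = {}
for fc in harmonized:
    g = build_graph(fc, threshold=0.0, age=float(info.loc[fc.subject_id, "age"]))
    graphs.setdefault(str(info.loc[fc.subject_id, "group"]), []).append(g)

results, summary = cross_validate(
    graphs["HC"],
    ModelConfig(in_dim=spec.n_regions, seed=0),
    TrainingConfig(n_epochs=40, k_folds=5, split_seed=0),
)
print(f"CV MAE  {summary['mae'][0]:.2f} +- {summary['mae'][1]:.2f} years")
print(f"CV PCC  {summary['pcc'][0]:.2f} +- {summary['pcc'][1]:.2f}")

report = evaluate_group(results, graphs["AD"], "AD")
print(f"AD brain age gap  {report.bag[0]:.2f} +- {report.bag[1]:.2f} years")
```

Output:

```
CV MAE  3.17 +- 1.12 years
CV PCC  0.95 +- 0.03
AD brain age gap  3.39 +- 0.34 years
```

The model predicts held-out control ages to ~3 years on this small cohort,
and the group planted with a +5-year brain-age offset shows a clearly
positive gap (attenuated below 5 by regression toward the mean — see
`docs/methods.md`). The ± values are dispersions across folds / fold
models.

A command-line interface mirrors the library:

```sh
brainage simulate --seed 1 --out cohort/
brainage fc --timeseries cohort/timeseries --out fc/
brainage harmonize --features fc/edge_vectors.csv --pheno cohort/phenotypes.csv --out harmonized.csv
brainage graphs --fc fc/ --pheno cohort/phenotypes.csv --threshold 0.0 --out graphs/
brainage train --graphs graphs/ --pheno cohort/phenotypes.csv --out models/
brainage bag --models models/ --graphs graphs/ --pheno cohort/phenotypes.csv --group AD
brainage explain --models models/ --graphs graphs/ --pheno cohort/phenotypes.csv --groups HC,AD --out explain/
```

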
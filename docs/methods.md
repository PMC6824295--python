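# Methods

`scdeconv` estimates the cell-type composition of bulk RNA-seq samples with
a neural network trained entirely on synthetic mixtures of single-cell
profiles. This note documents the model, the choices made where the design
was genuinely open, and what the synthetic benchmarks do and do not show.

## Overview of the procedure

Given an annotated single-cell reference (genes × cells, TPM or counts,
with a cell-type label per cell):

1. **ZINB modelling and oversampling.** Each gene is modelled as a
   zero-inflated negative binomial: counts `y ~ NB(μ, θ)` (variance
   `μ + μ²/θ`) zeroed with dropout probability `π`. The NB mean varies over
   the full design (cell type plus optional covariates such as sample or
   sex); `π` varies over cell type only; one `θ` is shared per gene. Types
   with few cells are augmented with simulated profiles (default: exactly
   1000 simulated cells per type, "fixed" mode; "fill" mode tops types up to
   the target instead).
2. **Splitting.** Cells are split 65/35 into train/test, stratified by
   type, so no cell contributes to both training and evaluation mixtures.
3. **Pseudo-bulk mixing.** Composition vectors `(w_1..w_k)`, `Σ w_k = 100`,
   are drawn under five schemes (truncated-uniform with per-type limits;
   the same label-permuted; uniform without repeated vectors; that
   permuted; Dirichlet). Each bulk sample mixes 100 cells drawn with
   replacement according to the (largest-remainder-rounded) weights; the
   bulk column is the per-gene mean, TPM-renormalized. The recorded truth
   is the realized integer composition.
4. **Training.** Features are `log2(TPM+1)` min-max scaled per gene to
   [0,1]. The network is `input → [dense(200) → batchnorm → ReLU →
   dropout(0.25)]×2 → dense(k) → softmax`, trained with Adam (lr 1e-3) on
   the Kullback–Leibler divergence `Σ t log(t/p̂)` for 50 epochs in batches
   of 100, truth rescaled to the simplex. By default the single-cell
   profiles of the training partition are appended as one-hot "bulk"
   columns, with the sample order shuffled each epoch.
5. **Evaluation.** Per-type and pooled Pearson correlation with a linear or
   quadratic fit of truth on prediction; Bland–Altman agreement (mean
   difference ± 1.96 sample SD); absolute proportional error
   `|p̂−p|/max(p, 0.1)` binned by expected proportion; per-sample maximum
   absolute/proportional errors; and quantile stratification of samples by
   a proportion ratio (e.g. CD8 over monocyte/macrophage content).

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| `target_per_type` | 1000 profiles | oversampling target per cell type |
| `train_frac` | 0.65 | stratified cell split |
| `cells_per_sample` | 100 cells | mixture size per pseudo-bulk sample |
| bulk samples per scheme | 2000 train / 700 test | configurable; the count is not intrinsic to the method |
| hidden layers | [200, 200] | with batchnorm, ReLU, dropout 0.25 |
| loss | KLD | MAE/MSE available |
| epochs × batch | 50 × 100 | more epochs tend to over-fit |
| θ bounds | [1e-3, 1e6] | during per-gene MLE, with `π ∈ [1e-6, 1−1e-6]` |
| proportional-error floor | 0.1 pp | avoids division by zero at p = 0 |

## Numerical choices

* **ZINB fitting.** Per-gene maximum likelihood via L-BFGS-B on
  (log μ per group, log θ, logit π per type), initialized by a
  method-of-moments estimate; zeros are collapsed into per-group counts so
  each likelihood evaluation is linear in the number of non-zero
  observations. Genes whose optimization fails keep the moment estimate and
  are flagged. All-zero genes get `μ = 1e-8`, `π = 1−1e-6` rather than an
  error. TPM values are rounded to integers for fitting; simulated draws
  are integer TPM-scale pseudo-counts, and TPM renormalization happens
  where profiles are consumed (bulk columns, one-hot columns), not inside
  the simulator — this keeps the simulator's output exactly NB-distributed
  and integer-valued.
* **Covariates.** μ uses the full design; π uses cell type only (fewer
  parameters keeps small groups stable). When simulating a cell, covariate
  levels are drawn from the empirical levels of that type's real cells.
* **Duplicate rejection (scheme 3/4).** "Without replacement" is
  interpreted as no duplicate composition vector within a set, after
  rounding to 0.1; with a single cell type the only vector is (100) and
  rejection is vacuous.
* **Rounding.** Weights are converted to integer cell counts by
  largest-remainder rounding with ties to the lower type index, so realized
  truth deviates from requested weights by at most 100/`cells_per_sample`
  per type.
* **Feature scaling.** The reference publication does not state a feature
  normalization; `log2(TPM+1)` with per-gene min-max was chosen for
  boundedness under a softmax head. Scaling parameters are frozen in the
  model artifact; at predict time features are clipped to [0,1] and the
  bulk matrix is TPM-renormalized over the model's gene list so train and
  predict features share a scale.
* **Gene matching** is exact-string; missing genes are zero-filled, more
  than 50% missing raises a warning flag in the alignment report and more
  than 90% (configurable) is an error.
* **Determinism.** Every stage takes a seed; the pipeline derives stage
  seeds as `sha256(global_seed, stage_name) mod 2^31`, so a rerun with one
  seed reproduces all artifacts.

## The synthetic benchmark and its limits

`fixtures.make_ground_truth` generates the reference dataset used
throughout testing: 5 types × 500 genes × 600 cells per type by default,
base means log-uniform on [0.5, 50], dispersions uniform on [0.5, 4],
dropout uniform on [0.1, 0.6], and 10 marker genes per type with an 8-fold
mean increase — magnitudes typical of moderately sequenced tumor scRNA-seq.
It emulates type-specific means, overdispersion, dropout and markers; it
does **not** emulate batch effects, doublets, ambient RNA or library-size
variation, so passing benchmarks demonstrate the machinery recovers known
compositions under the assumed noise model, not robustness to those
artifacts on real tissue.

`experiments.recovery_experiment` runs the whole pipeline on this fixture
(3000 training / 1000 test mixtures, sizes chosen so the run completes in
about half a minute on one CPU) and reaches pooled Pearson r ≈ 0.97 with
per-type Bland–Altman mean differences well inside ±2 percentage points.

**One-hot columns and calibration.** With this fixture's heavy dropout,
co-training on one-hot single-cell columns introduces per-type calibration
biases on interior mixtures (per-type r stays ≥ 0.95 but slopes and offsets
drift by several percentage points). This mirrors the calibration
distortion the method is known to show on some real datasets, where a
square-root rescaling of predictions (`calibrate_sqrt`, provided but never
auto-applied) restores agreement. The recovery experiment therefore trains
on the bulk mixtures alone — its sample budget is specified in bulk
mixtures — while the standard pipeline keeps one-hot inclusion on by
default, matching the published training procedure.

## Known limitations

* Per-gene ZINB MLE is independent across genes; no information sharing
  (e.g. dispersion shrinkage) is attempted, so dispersion estimates for
  near-silent genes are noisy.
* The latent-factor part of ZINB-WaVE-style models (sample-level `W`) is
  out of scope; covariates enter only as fixed categorical effects.
* Gene identifiers are never translated between annotation styles.
* Survival statistics (Kaplan–Meier, log-rank) are out of scope:
  `ratio_stratify` exports group labels for off-the-shelf survival tools.
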
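# Methods

## Problem and model

The package classifies subjects as patient (SCZ, label 1) or healthy
control (HC, label 0) from voxel-based-morphometry maps: spatially
normalized gray- or white-matter density volumes on a shared grid, values
approximately in [0, 1]. Each subject is a point in the space of masked
voxels; the classifier is a two-stage pipeline — univariate voxel screening
by mutual information, then a small dense network with a sparsity penalty —
so that the final decision remains attributable to a named set of voxels.

### Analysis mask

The mask keeps voxels whose across-subject mean ≥ `min_mean` (default
0.05) and variance > `min_variance` (default 0, strict). This is a
pragmatic stand-in for an anatomical brain mask: it removes empty
background and constant voxels, which carry no information and would
produce degenerate bins. Inside `run_pipeline` the mask is computed on the
training split only, so held-out subjects never influence feature
definition. Raising either threshold is monotone (never adds voxels).

### Mutual-information screening

Continuous densities enter the discrete MI formula through equal-frequency
(quantile) binning, default `n_bins = 4`; a value equal to a cut point
falls in the lower bin, and a constant column degrades to a single code
(MI = 0) rather than erroring. The estimator is the plug-in one over the
empirical joint table, natural log, with 0·log 0 := 0 and tiny negative
rounding clipped to 0. For a binary label, 0 ≤ I(X,Y) ≤ H(Y) ≤ ln 2; both
bounds are asserted in tests, and the vectorized implementation is checked
against a brute-force double sum on random small instances. Quantile bins
were chosen over equal-width bins because VBM densities are skewed near
tissue boundaries; the bin count trades bias (few bins) against estimator
noise at cohort-scale n (many bins) — at n = 60, four bins leave ≥ 15
subjects per cell in expectation.

Voxels are ranked by MI, descending, ties broken by ascending column index
so selection is deterministic. `k` is configurable (default 200 at phantom
scale, 2000 intended for full-resolution grids); ranking happens on the
training split and the chosen columns are frozen before training.

### The KL–L1 penalty

For each weight row, p_i = ‖W_i·‖₁ is treated as a Bernoulli parameter and
penalized by KL(p_i ‖ ε) = p_i log(p_i/ε) + (1−p_i) log((1−p_i)/(1−ε)),
summed over the rows of both layer matrices (biases excluded — the norm
semantics belong to rows of weights). ε defaults to 0.05, λ (the weight of
the penalty against cross-entropy) to 1e-3.

The Bernoulli KL needs p ∈ (0, 1) while raw L1 norms are unbounded, so the
penalty evaluates the formula at the row norm clipped to [δ, 1−δ],
δ = 1e-6. The gradient is the exact gradient of that clipped function —
zero in the flat clipped region. Two numerical choices keep this honest in
practice:

- **Initialization inside the domain.** Weight rows are initialized with
  L1 norm 0.5 (random signs/directions), so training starts where the
  penalty is differentiable and the flat region is essentially never
  visited. With a variance-scaled init (row norms ≫ 1) the penalty would
  be silently inactive.
- **Feature standardization.** Features are z-scored with training-split
  statistics stored on the model (`standardize = True` by default).
  Smoothed density maps have per-voxel SDs of order 0.04; with row norms
  capped near ε the attainable logits on raw features are ~1e-3, and the
  optimizer can fall into the trivial p ≡ 0.5 minimum (observed: training
  accuracy pinned at chance with perfect AUC, all row norms collapsed to
  ε). Standardization restores a sensible scale ratio between signal and
  penalty. A warm-started model reuses its source scaler so inherited
  weights keep their meaning across cohorts.

The penalty is 0 iff every clipped row norm equals ε, and its analytic
gradient matches finite differences to 1e-5 relative in tests. With λ
large, trained row norms approach ε (tested against λ = 0).

### Network and training

Architecture: k inputs → dense(n_hidden = 64, ReLU) → dense(1, logistic).
Loss: mean binary cross-entropy + λ·[penalty(W1) + penalty(W2)]. Optimizer:
Adam (β₁ = 0.9, β₂ = 0.999, lr 1e-3), mini-batches (default 32; 16 in the
phantom protocol) shuffled by a seeded generator, up to `max_epochs`
(default 500) with early stopping after 50 epochs without training-loss
improvement; the returned parameters are those of the best training-loss
epoch. `max_epochs = 0` is allowed and returns the warm-start weights
unchanged (used to reduce transfer retraining to frozen evaluation).
Everything is reproducible bit-for-bit from the config seed. The class
threshold is 0.5 with ≥ breaking ties toward the patient class.

GM and WM are independent end-to-end models; the combined verdict averages
the two probabilities (threshold 0.5). The averaging rule is deliberately
simple and pluggable.

### Evaluation protocol

Splits are stratified by diagnosis: the training set size is
round(fraction·n), allocated across classes by largest remainder, so class
proportions stay within one subject of the target (400 balanced subjects
at 0.875 → 350/50; 132 subjects at 92/132 → 92/40). Metrics come from the
confusion table; any quantity with a zero denominator is flagged None, and
NNP = 1/(PPV + NPV − 1) is None whenever the predictive summary index is
≤ 0 (a classifier no better than chance has no finite NNP). ROC curves use
a threshold sweep with ties entering simultaneously; the trapezoidal AUC
then equals the pairwise-concordance (Mann–Whitney) estimator, which the
tests verify independently. CIs are subject-level percentile bootstraps
(default 2000 resamples, seeded; resamples that lose a class are redrawn
for class-conditional metrics).

Transfer retraining mirrors a two-cohort study: the frozen model is first
evaluated on the entire new cohort ("unseen"), then retrained —
warm-started from the frozen weights — on the new cohort's training split
and evaluated on its test split.

### Saliency

Reference means/SDs per voxel and group are computed on the training
cohort (sample SD, n−1); zero-SD voxels are flagged and excluded. For a
subject value v, z_HC = (v − mean_HC)/sd_HC, z_SCZ = (v − mean_SCZ)/sd_SCZ,
combined = z_SCZ/(z_SCZ + z_HC). The combined score is computed exactly as
defined: it is 0 at the patient mean, 0.5 where both standardizations
agree, 1 at the control mean, and unbounded in general — published
renderings of such maps appear bounded, which suggests a post-hoc
transform; we deliberately do not bound it. Denominators below 1e-8 mark
the voxel undefined (NaN in the exported map, counted in the JSON
sidecar). Maps are written only at the model's selected voxels, background
0.

## The phantom generator

The generator emulates a two-group VBM case-control cohort: a constant
baseline density (0.5) plus Gaussian noise (SD 0.1), patients additionally
losing `effect`·noise_sd density inside spherical blobs, everything then
Gaussian-smoothed (FWHM 2 voxels) and clipped to [0, 1]. The effect is
injected *before* smoothing so lesion edges blur like partial-volume
effects do. Defaults (24³ grid ≈ 14k voxels, 30 subjects/group, one
radius-3 blob, effect 2.0) keep a full two-tissue pipeline run under a
minute on one CPU while preserving the study's qualitative regime: a
separable but noisy high-dimensional problem with ~200 truly informative
voxels.

What the phantom does **not** emulate: brain anatomy and tissue geometry,
inter-subject registration error, scanner/site effects, age/sex
covariates, spatially varying noise. Passing tests therefore demonstrate
the correctness and statistical behavior of the pipeline — feature
recovery, calibration under the null, power at a known effect size — not
clinical-grade accuracy on real cohorts.

In the transfer (drift) experiment, the new cohort's drift is an
*attenuated lesion effect* (2.0 → 1.0 SD). A uniform baseline-intensity
shift turns out not to degrade the trained network at all — weight rows
have mixed signs, so a constant offset largely cancels in every hidden
unit — whereas effect attenuation reproduces the characteristic pattern of
an unseen-cohort evaluation: frozen-model accuracy drops to ~0.77 and
recovers to ~1.0 after warm-started retraining at phantom scale.

## Problem sizes used in the validation suite

The suite runs phantom cohorts of 20–60 subjects on 12³–24³ grids, MI
oracle checks at n ≤ 50, AUC oracle checks at n ≤ 30, bootstrap coverage
over 200 simulated test sets of 50 subjects (400 resamples each), and a
25-seed null-calibration check. The acceptance script trains one model on
52 training subjects × 200 voxels. These sizes were chosen so the whole
battery runs in well under a minute per module on a single CPU.

## Known limitations

- The published account of this model family leaves ε, λ, layer width,
  optimizer and the bin count unstated; our defaults are declared above
  and in `EDNNConfig`, and all are logged per run. Results at other
  settings may differ.
- The KL–L1 row-norm domain problem (norms are not probabilities) is
  resolved by clipping + in-domain initialization; a normalized-row-norm
  variant is plausible but not implemented.
- Whether the penalty should cover both layers or only the first is
  ambiguous; we penalize both (θ is the full parameter set).
- The combined saliency score is reported unbounded, as defined, with
  undefined-voxel flagging; consumers expecting [0, 1] maps must transform
  it themselves.
- Single-split test metrics at phantom scale are high-variance (n_test as
  small as 8); seed-averaged checks are used where stability matters.
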
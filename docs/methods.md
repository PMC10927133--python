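# Methods

## Problem setting

`radiofusion` models a radiogenomics workflow for predicting a binary driver
mutation status (wildtype = 0, mutation = 1) from two modalities: a 2-D
grayscale lesion image (a CT-slice stand-in) and a gene-expression vector.
Annotated masks are expensive, so only a fraction of training images carry
labels and masks; the rest are unlabeled. The package couples three
mechanisms:

1. **Supervised segmentation pretraining.** An encoder–bridge–decoder
   network with attention-fused skip connections is trained on the labeled
   image/mask pairs (Dice + binary cross-entropy loss). Segmentation teaches
   the shared body to localize lesions and suppress background texture.
2. **Parameter sharing.** The classifier ("student") re-uses the entire
   segmentation body — stem, three SE-ResNeXt encoders, SE-ResNeXt + ASPP
   bridge, three attention-fused decoders — with weights copied bit-for-bit
   from the segmentation checkpoint and then fine-tuned.
3. **Mean-Teacher semi-supervision.** A teacher model, the exponential
   moving average (EMA) of the student's weights
   (`w_t <- alpha*w_t + (1-alpha)*w_s` per optimizer step), scores
   noise-perturbed unlabeled samples; the squared gap between student and
   teacher probabilities is added to the supervised loss with a
   sigmoid-shaped ramp weight `w(t) = w_max * exp(-5 (1 - t/T)^2)` over the
   first `T` ramp-up epochs. The final student makes predictions.

## Network components

**SE-ResNeXt block.** 1x1 conv → grouped 3x3 conv (`cardinality` groups) →
1x1 conv, batch-norm + ReLU between stages, a squeeze-and-excitation gate
(global average pool → bottleneck of ratio `se_reduction` → sigmoid
per-channel gate) on the branch, residual addition with a 1x1 projection
shortcut when widths differ. Defaults: cardinality 8, SE reduction 4 (both
configurable; tests and desk-scale runs use cardinality 2 with narrow
widths).

**ASPP bridge.** Parallel 3x3 convolutions at dilations (3, 6, 9) plus a
1x1 branch and an image-pooling branch, concatenated and 1x1-projected.
When the bridge grid is not larger than a dilation rate, that branch is
dropped with a warning and contributes zero channels — at a 4x4 bridge only
the dilation-3 branch survives, which is the intended degradation at small
image sizes.

**Attention-gated skip fusion.** For each decoder level, the low-level
encoder feature `F_low` (C_low, H, W) and the bilinearly 2x-upsampled
deeper feature `F_high` are concatenated; a shared one-hidden-layer MLP
(reduction ratio 4) maps both the global average pool and the global max
pool of the concatenation; their sum through a sigmoid gives per-channel
coefficients `W_global`. Gate maps are `sigmoid(F_high + g_high)` and
`sigmoid(F_low + g_low)` where the guidance vectors split by the
concatenation order — the first C_low entries (from the max-pool branch)
gate the low stream, the last C_high entries (from the average-pool branch)
gate the high stream — broadcast per channel over the grid. Gated residuals
`x*sigmoid(.) + x` keep each feature's sign with magnitude in [|x|, 2|x|].
The `W_global`-scaled concatenation is 1x1-projected to the level width.
The guidance-vector split is the single most consequential interpretation
in the module: it preserves the channel correspondence established by the
concatenation. A `gate_mode="channel"` flag replaces the spatially resolved
gates with per-channel scalars pooled first (the alternative reading).

**Intra fusion.** The three decoder features (at H/4, H/2, H) are each
average-pooled to the coarse classification grid (H/8), 1x1-projected to the
classification width, and fused with the initial classification feature
`F_cls` (itself obtained by pooling the finest decoder feature to H/8
followed by 3x3 conv + BN + ReLU). Per level, the initial fusion is
`F_sc = conv3(F_seg') + conv3(F_cls)`, then three 3x3 conv stages where
each stage input re-adds `F_sc` — so shallow information is re-injected at
every depth (a MultiRes-style chain).

**Inter fusion.** The three intra-fused maps, `F_cls` and the gene
embedding tiled over the grid are channel-concatenated and 1x1-projected to
C channels. Query/Key/Value each come from a single-channel 3-tap
convolution along one axis of the (C, H, W) feature volume — height for
Query, channel for Key, width for Value — followed by BN + ReLU; this
realizes 1x3x1 / 3x1x1 / 1x1x3 kernels over the volume. A conventional 2-D
alternative sits behind `qkv_mode="conv2d"`. The attention matrix is
`A = softmax(Q^T K)` normalized over its first index, so every column is a
probability vector and each output position receives a convex combination
of input positions; `Value @ A` is added residually to the projected stack.
Attention cost is quadratic in H*W; a configurable cap (default 4096
positions) raises an explicit resource error advising pooling first. The
three axis orientations carry no anatomical meaning for 2-D slices; they
are three complementary 1-D mixing directions of the feature volume.

**Gene pipeline.** Genes are screened on *labeled training samples only* by
absolute point-biserial correlation with the label (mutual information
available behind the same interface); constant genes score exactly 0; ties
break by column index; top-k kept (default k = 115). A per-gene z-score
scaler is fitted on the same samples. Screened vectors pass through a
two-layer MLP (k → 64 → 32 by default) trained jointly with the classifier.

**Classification head.** Global average pool of the inter-fused map →
fully connected → sigmoid.

## Numerical engine

No GPU tensor library is part of the package's dependency set; the networks
run on a small reverse-mode autograd engine over numpy arrays
(`radiofusion.autograd`, `radiofusion.nn`). Design constraints that shaped
it:

* all convolutions are stride 1 (pooling downsamples, bilinear interpolation
  upsamples), which lets the convolution input-gradient be expressed as
  another convolution with the channel-swapped, spatially flipped kernel;
* bilinear 2x upsampling is a separable linear map applied as cached
  matrices, so its backward pass is the exact adjoint;
* binary cross-entropy is computed on logits in the overflow-safe
  `softplus(z) - y*z` form;
* max-pool gradients route to the (first) argmax; the generic `max`
  reduction splits ties evenly so finite-difference checks are well defined;
* every operator's gradient is verified against central differences in
  `tests/test_autograd.py`.

Optimization uses Adam (lr 0.001 by default, the standard
beta/epsilon constants). Batch norm uses batch statistics in training and
running averages (momentum 0.1) in evaluation; EMA averaging covers running
statistics as well as weights.

## Synthetic phantom cohort

The generator emulates the structure of a CT + RNA-seq cohort:

* **Labels.** Bernoulli(`mutation_fraction`), default 0.4 — class-balanced
  enough that stratified splits stay stable at small cohort sizes while
  still prevalence-skewed like real mutation cohorts.
* **Images.** 64x64 by default (any multiple of 8), background level 0.15
  plus Gaussian noise (sd 0.08 default), one elliptical lesion per image
  with semi-axes drawn from `lesion_radius_range`, random orientation and
  position, painted at `lesion_contrast` (0.5 default) above background.
* **Class signal in images.** Inside the mask, class 1 receives a texture
  term with mean `0.5 * texture_shift` and sd `0.25 * texture_shift`;
  class 0 receives none. `texture_shift = 0` makes classes
  image-indistinguishable by construction.
* **Genes.** `n_genes` (500 default) standard-normal expression values;
  the first `n_informative` (20) get a class-1 mean shift of `gene_effect`
  standard deviations. `gene_effect = 0` removes all gene signal.
* **Splits.** Test fraction 0.2 (4:1 train/test), stratified by class;
  within training, `labeled_fraction` (0.30 default) of each class is
  labeled — stratification avoids degenerate single-class labeled sets at
  small n. Every sample is rendered from its own counter-based random
  stream (`default_rng([seed, index])`), so cohorts are pure functions of
  (config, seed) and invariant to generation order.

What the phantoms do **not** emulate: 3-D volumes, Hounsfield calibration,
anatomical context, correlated gene modules, batch effects, class-dependent
lesion shape. Passing tests therefore demonstrate that the architecture,
losses and training loop behave as specified and can extract planted
image/gene signals — not clinical performance.

## Study designs used by the test suite

Problem sizes were chosen so the full suite runs on one desktop CPU core;
thresholds are fixed contracts.

* **Segmentation smoke.** A single sample is memorized to Dice ≥ 0.99
  within 200 steps; 200 noiseless high-contrast phantoms at 64x64
  (8 epochs, lr 2e-3, widths 8/8-16-16/32) reach test Dice ≥ 0.95.
* **End-to-end smoke.** 400 phantoms at 32x32 with gene_effect 2,
  texture_shift 0.3, 30% labels: segmentation pretraining (3 epochs) →
  screening (k = 115) → Mean-Teacher training (6 epochs, ramp 3,
  alpha 0.95) must reach test AUC ≥ 0.85.
* **Ablation directions** (5 paired seeds, 160 phantoms at 16x16). Each
  comparison runs under conditions where its mechanism is observable rather
  than ceiling-saturated: image+gene vs image-only uses a weak image signal
  (texture_shift 0.1) with the strong gene effect; consistency vs pure
  supervision uses moderate signal in both modalities (gene_effect 0.8,
  texture_shift 0.15); pretrained vs random-init encoder uses image-only
  classification over a noisier background (sd 0.15) with deliberately
  short classifier training (3 epochs), where initialization matters most.
  Only mean orderings are asserted, never magnitudes.
* **Null control.** With gene_effect 0 and texture_shift 0 the 5-seed mean
  test AUC must stay in [0.4, 0.6], guarding against label leakage anywhere
  in the pipeline (screening, splits, training).

## Degenerate inputs and edge behavior

* Undefined metric ratios (zero denominators) are reported as missing with
  a warning, never NaN-propagated; AUC on a single-class sample is flagged
  undefined.
* AUC ties count 1/2, which makes the trapezoid and pairwise definitions
  coincide exactly (asserted to 1e-9).
* Constant genes score 0 and can only be selected after all non-constant
  genes at equal score, by index order.
* An empty labeled split raises a data error; an empty unlabeled split
  degrades to supervised training with a logged warning.
* Images whose sides are not multiples of 8 raise a shape error suggesting
  padding; lesions that cannot be placed after 100 attempts raise a
  generation error.

## Known limitations

* The numpy engine is single-threaded and desk-scale; the default channel
  plan (16/32-64-128/128) is already slow at 512x512 — the package is a
  faithful, testable implementation of the architecture, not a production
  trainer.
* The 8-bit PNG dialect quantizes images to 1/255; round-trips are
  idempotent after one write/load cycle but not bit-exact against the
  in-memory float cohort.
* Deep supervision, multi-head attention, spatial attention variants,
  AutoAugment-style policy search and 3-D inputs are out of scope; image
  augmentation for the consistency loss is additive Gaussian noise only.
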
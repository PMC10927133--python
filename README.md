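# radiofusion

Segmentation-assisted, semi-supervised multimodal classification of lesion
phantoms — a desk-scale radiogenomics pipeline that fuses 2-D lesion images
with gene-expression profiles to predict a binary mutation status
(wildtype vs mutation) when only a fraction of the training images carry
labels and masks.

**Who it is for.** Researchers who want a fully testable, CPU-only
implementation of the "segmentation helps classification" + Mean-Teacher +
imaging-genomics fusion recipe: every component is exercised end-to-end on a
bundled synthetic phantom generator, with no external downloads.

## The model

Two networks share one convolutional body
(stem → 3 SE-ResNeXt encoders → SE-ResNeXt + ASPP bridge → 3 decoders with
attention-gated skip fusion):

1. **Segmentation network** — trained on labeled image/mask pairs with
   Dice + BCE loss; its attention-gated skips fuse a low-level feature
   F_low with the upsampled high-level feature F_high through per-channel
   guidance W_global = σ(MLP(GAP(F_C)) ⊕ MLP(GMP(F_C))) and gated residuals
   x ⊗ σ(·) ⊕ x.
2. **Student classifier** — initialized from the segmentation checkpoint
   (bit-identical body weights), it pools the decoder features to a coarse
   grid, fuses them level-by-level with the classification feature
   (intra fusion), concatenates the gene embedding G (screened top-k genes →
   MLP) into a multimodal stack, and applies non-local attention
   F_Inter = M_C ⊕ softmax(QᵀK) ⊗ V with column-stochastic A (inter
   fusion), followed by GAP → FC → σ.

Semi-supervision follows the Mean-Teacher scheme: the teacher's weights are
the EMA of the student's, w_t ← α·w_t + (1−α)·w_s, and a ramped MSE
consistency term ties student and teacher predictions on noise-perturbed
unlabeled samples. Evaluation reports accuracy, recall, precision,
specificity, AUC (trapezoid = pairwise P(X₁>X₀) + ½·ties) and F1.

The networks run on a small, fully gradient-checked numpy autograd engine
(`radiofusion.autograd` / `radiofusion.nn`) — no GPU framework required.

## Worked example

```python
import dataclasses
from radiofusion import nn
from radiofusion.backbone import BackboneConfig
from radiofusion.phantom import PhantomConfig, generate_cohort
from radiofusion.segnet import SegModel, SegTrainConfig, train_segmentation
from radiofusion.genes import select_genes
from radiofusion.mean_teacher import (ClassifierConfig, SemiTrainConfig,
                                      build_student, make_pair, predict,
                                      train_semisupervised)
from radiofusion.metrics import evaluate_predictions

# 400 phantoms at 32x32: strong gene effect, moderate image texture shift,
# 30% of training samples labeled, 4:1 train/test split
cohort = generate_cohort(PhantomConfig(
    n_samples=400, image_size=32, lesion_radius_range=(4, 9),
    gene_effect=2.0, texture_shift=0.3, labeled_fraction=0.3, seed=1))

bb = BackboneConfig(stem_channels=4, encoder_channels=(8, 8, 16),
                    bridge_channels=16, cardinality=2, se_reduction=2)
nn.manual_seed(1)
seg = SegModel(bb)
seg, _ = train_segmentation(seg, cohort, SegTrainConfig(
    epochs=3, batch_size=16, learning_rate=2e-3, seed=1))

lab = cohort.split["train_labeled"]
screen = select_genes(cohort.expression_matrix()[lab],
                      cohort.labels(lab).astype(int), k=115)
nn.manual_seed(2)
student = build_student(seg.state_dict(), bb,
                        ClassifierConfig(cls_channels=8, gene_hidden=32,
                                         gene_embed=16), gene_k=screen.k)
pair = make_pair(student, alpha=0.95)
student, _ = train_semisupervised(pair, cohort, screen, SemiTrainConfig(
    epochs=6, batch_size=16, rampup_epochs=3, alpha=0.95, seed=1))

te = cohort.split["test"]
probs = predict(student, cohort.images(te), screen.transform(cohort.genes(te)))
print(evaluate_predictions(cohort.labels(te), probs).as_percent_dict())
```

A run of this experiment (seed 1) prints

```
{'accuracy': 98.75, 'recall': 96.97, 'precision': 100.0,
 'specificity': 100.0, 'auc': 99.87, 'f1': 98.46}
```

i.e. with 20 informative genes shifted by 2 SD and only 96 labeled training
samples, the fused student separates the test set almost perfectly — while
the built-in null control (no gene effect, no texture shift) stays at
chance (AUC ≈ 49%), confirming that nothing leaks labels.

The same pipeline is available from the shell:

```bash
radiofusion synth        --n 400 --seed 1 --out data/
radiofusion pretrain-seg --manifest data/manifest.csv --out seg.ckpt
radiofusion train-cls    --manifest data/manifest.csv --seg-checkpoint seg.ckpt --out cls.ckpt
radiofusion predict      --model cls.ckpt --manifest data/manifest.csv --sample-id sample_00000
radiofusion evaluate     --model cls.ckpt --manifest data/manifest.csv --out report.json
```

## Layout

| module | contents |
|---|---|
| `radiofusion.phantom` | synthetic cohort generator (images, masks, labels, expression, splits) |
| `radiofusion.autograd`, `radiofusion.nn` | numpy autograd engine, layers, Adam |
| `radiofusion.backbone` | SE-ResNeXt blocks, ASPP bridge, stem, encoder/decoder blocks |
| `radiofusion.attention_fusion` | attention-gated skip fusion (+ plain-concat ablation) |
| `radiofusion.segnet` | segmentation network assembly and trainer |
| `radiofusion.genes` | gene screening (point-biserial / mutual information) and embedding MLP |
| `radiofusion.multimodal` | intra-level fusion, non-local inter-modality attention, head |
| `radiofusion.mean_teacher` | student/teacher pair, EMA, semi-supervised trainer, predict |
| `radiofusion.metrics` | confusion counts, six-metric report, dual-route AUC, k-fold harness |
| `radiofusion.io_utils`, `radiofusion.cli` | PNG/NIfTI/CSV/YAML/JSON I/O, checkpoints, CLI |
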
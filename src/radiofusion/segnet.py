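"""Supervised multilevel-fusion segmentation network.

Topology: stem -> three SE-ResNeXt encoders (each followed by 2x2 max pool)
-> SE-ResNeXt + ASPP bridge -> three decoders, each fed by the attention
fusion of the matching encoder skip with the upsampled deeper feature ->
1x1 conv + sigmoid output head.  For an HxW input (H, W divisible by 8) the
decoder features sit at H/4, H/2 and H — these are the segmentation features
later shared with the classifier.

Training minimizes equally weighted Dice + binary cross-entropy on the
labeled masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention_fusion import AttentionFusion, ConcatFusion
from .autograd import Tensor, bce_with_logits, no_grad
from .backbone import ASPP, BackboneConfig, DecoderBlock, EncoderBlock, SEResNeXtBlock, Stem
from .metrics import dice_coefficient
from .phantom import PhantomCohort


class ShapeError(ValueError):
    pass


class SegModel(nn.Module):
    """Encoder–bridge–decoder segmentation model with attention-fused skips."""

    def __init__(self, cfg: BackboneConfig | None = None, fusion: str = "attention"):
        super().__init__()
        cfg = cfg or BackboneConfig()
        self.cfg = cfg
        c0 = cfg.stem_channels
        c1, c2, c3 = cfg.encoder_channels
        cb = cfg.bridge_channels
        self.stem = Stem(1, c0)
        self.enc1 = EncoderBlock(cfg.level_cfg(c0, c1))
        self.enc2 = EncoderBlock(cfg.level_cfg(c1, c2))
        self.enc3 = EncoderBlock(cfg.level_cfg(c2, c3))
        self.bridge_block = SEResNeXtBlock(cfg.level_cfg(c3, cb))
        self.bridge_aspp = ASPP(cb, cb, cfg.aspp_dilations)
        fusion_cls = AttentionFusion if fusion == "attention" else ConcatFusion
        # decoder level i fuses encoder skip i with the deeper decoder output
        self.fuse3 = fusion_cls(c3, cb, c3)
        self.dec3 = DecoderBlock(cfg.level_cfg(c3, c3))
        self.fuse2 = fusion_cls(c2, c3, c2)
        self.dec2 = DecoderBlock(cfg.level_cfg(c2, c2))
        self.fuse1 = fusion_cls(c1, c2, c1)
        self.dec1 = DecoderBlock(cfg.level_cfg(c1, c1))
        self.head = nn.Conv2d(c1, 1, kernel=1)

    # ------------------------------------------------------------------
    def forward_features(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Return (logit map, [F_S^1 at H/4, F_S^2 at H/2, F_S^3 at H])."""
        B, C, H, W = x.shape
        if H % 8 or W % 8:
            raise ShapeError(f"input spatial size {H}x{W} must be divisible by 8 "
                             "(pad the image first)")
        s0 = self.stem(x)
        f1, p1 = self.enc1(s0)        # f1 @ H,   p1 @ H/2
        f2, p2 = self.enc2(p1)        # f2 @ H/2, p2 @ H/4
        f3, p3 = self.enc3(p2)        # f3 @ H/4, p3 @ H/8
        bridge = self.bridge_aspp(self.bridge_block(p3))   # @ H/8
        d3 = self.dec3(self.fuse3(f3, bridge))             # @ H/4
        d2 = self.dec2(self.fuse2(f2, d3))                 # @ H/2
        d1 = self.dec1(self.fuse1(f1, d2))                 # @ H
        return self.head(d1), [d3, d2, d1]

    def forward(self, x: Tensor) -> Tensor:
        logits, _ = self.forward_features(x)
        return logits.sigmoid()


def segment(model: SegModel, images: np.ndarray):
    """Probability maps + decoder features for a (B,1,H,W) batch (eval mode)."""
    model.eval()
    with no_grad():
        logits, feats = model.forward_features(Tensor(np.asarray(images, dtype=np.float32)))
        prob = logits.sigmoid()
    return prob.data, [f.data for f in feats]


# ---------------------------------------------------------------------------


@dataclass
class SegTrainConfig:
    epochs: int = 20
    learning_rate: float = 0.001   # Adam
    batch_size: int = 16
    dice_w: float = 1.0
    bce_w: float = 1.0
    val_fraction: float = 0.10
    seed: int = 0

    def validate(self):
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs, learning_rate and batch_size must be positive")
        return self


def dice_loss(prob: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss over the batch."""
    t = Tensor(np.asarray(target, dtype=np.float32))
    inter = (prob * t).sum()
    denom = prob.sum() + t.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def seg_loss(logits: Tensor, target: np.ndarray, cfg: SegTrainConfig) -> Tensor:
    prob = logits.sigmoid()
    return cfg.dice_w * dice_loss(prob, target) + cfg.bce_w * bce_with_logits(logits, target)


class DataError(ValueError):
    pass


def train_segmentation(model: SegModel, cohort: PhantomCohort,
                       cfg: SegTrainConfig | None = None):
    """Train on the labeled training split; returns (model, history).

    history = {"loss": per-epoch mean training loss,
               "val_dice": per-epoch mean validation Dice at threshold 0.5}.
    """
    cfg = (cfg or SegTrainConfig()).validate()
    labeled = np.asarray(cohort.split["train_labeled"])
    if len(labeled) == 0:
        raise DataError("no labeled training samples with masks")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(int(round(cfg.val_fraction * len(labeled))), 1) if len(labeled) > 1 else 0
    perm = rng.permutation(labeled)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = perm, perm[:0]
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"loss": [], "val_dice": []}
    for _epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            x = Tensor(cohort.images(batch))
            logits, _ = model.forward_features(x)
            loss = seg_loss(logits, cohort.masks(batch), cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        if len(val_idx):
            prob, _ = segment(model, cohort.images(val_idx))
            dices = [dice_coefficient(prob[i, 0] >= 0.5, cohort.masks(val_idx)[i, 0] >= 0.5)
                     for i in range(len(val_idx))]
            history["val_dice"].append(float(np.mean(dices)))
        else:
            history["val_dice"].append(float("nan"))
    return model, history


def evaluate_dice(model: SegModel, cohort: PhantomCohort, idx,
                  batch_size: int = 16) -> float:
    """Mean Dice of thresholded predictions over the given indices."""
    idx = np.asarray(idx)
    dices = []
    for start in range(0, len(idx), batch_size):
        b = idx[start:start + batch_size]
        prob, _ = segment(model, cohort.images(b))
        masks = cohort.masks(b)
        dices += [dice_coefficient(prob[i, 0] >= 0.5, masks[i, 0] >= 0.5)
                  for i in range(len(b))]
    return float(np.mean(dices))
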
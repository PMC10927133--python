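"""Shared convolutional building blocks.

SE-ResNeXt residual blocks (grouped convolution + squeeze-and-excitation
channel gating), an atrous-spatial-pyramid-pooling bridge, the stem, and the
encoder/decoder blocks used by both the segmentation network and the student
classifier.  All convolutions are stride 1; spatial downsampling happens only
in the encoders' 2x2 max pooling, upsampling only in the decoders' bilinear
2x interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, concat, maxpool2x
from .nn import global_avg_pool


@dataclass(frozen=True)
class BlockConfig:
    in_channels: int
    out_channels: int
    cardinality: int = 8
    se_reduction: int = 4
    aspp_dilations: tuple[int, ...] = (3, 6, 9)

    def validate(self) -> "BlockConfig":
        if self.out_channels % self.cardinality:
            raise ValueError(f"out_channels={self.out_channels} not divisible by "
                             f"cardinality={self.cardinality}")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        if list(self.aspp_dilations) != sorted(set(self.aspp_dilations)):
            raise ValueError("aspp_dilations must be strictly increasing")
        return self


class SEGate(nn.Module):
    """Squeeze-and-excitation: GAP -> bottleneck -> sigmoid per-channel gate."""

    def __init__(self, ch: int, reduction: int = 4):
        super().__init__()
        hidden = max(ch // reduction, 1)
        self.fc1 = nn.Linear(ch, hidden)
        self.fc2 = nn.Linear(hidden, ch)

    def gates(self, x: Tensor) -> Tensor:
        s = global_avg_pool(x)                      # (B, C)
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        B, C = g.shape
        return x * g.reshape(B, C, 1, 1)


class SEResNeXtBlock(nn.Module):
    """Grouped-convolution residual branch with SE gating.

    1x1 reduce -> grouped 3x3 (cardinality groups) -> 1x1 expand, BN+ReLU
    between stages, SE gate on the branch output, residual addition (1x1
    projection shortcut when channel counts differ), final ReLU.
    """

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        cfg.validate()
        cin, cout, card = cfg.in_channels, cfg.out_channels, cfg.cardinality
        self.cfg = cfg
        self.conv_in = nn.Conv2d(cin, cout, kernel=1)
        self.bn_in = nn.BatchNorm2d(cout)
        self.conv_grp = nn.Conv2d(cout, cout, kernel=3, groups=card)
        self.bn_grp = nn.BatchNorm2d(cout)
        self.conv_out = nn.Conv2d(cout, cout, kernel=1)
        self.bn_out = nn.BatchNorm2d(cout)
        self.se = SEGate(cout, cfg.se_reduction)
        self.shortcut = nn.Conv2d(cin, cout, kernel=1, bias=False) if cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        h = self.bn_in(self.conv_in(x)).relu()
        h = self.bn_grp(self.conv_grp(h)).relu()
        h = self.bn_out(self.conv_out(h))
        h = self.se(h)
        sc = x if self.shortcut is None else self.shortcut(x)
        return (h + sc).relu()


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel dilated 3x3 branches plus a
    1x1 branch and an image-pooling branch, concatenated and 1x1-projected.

    Dilations larger than or equal to the spatial size are dropped with a
    warning (the dilated kernel would fold onto padding only).
    """

    def __init__(self, in_ch: int, out_ch: int, dilations: tuple[int, ...] = (3, 6, 9)):
        super().__init__()
        self.dilations = tuple(dilations)
        self.conv1 = nn.Conv2d(in_ch, out_ch, kernel=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.branches = nn.ModuleList(
            [nn.Conv2d(in_ch, out_ch, kernel=3, dilation=d) for d in self.dilations])
        self.branch_bns = nn.ModuleList([nn.BatchNorm2d(out_ch) for _ in self.dilations])
        self.pool_fc = nn.Linear(in_ch, out_ch)
        self._warned: set = set()
        n_branches = 2 + len(self.dilations)
        self.project = nn.Conv2d(n_branches * out_ch, out_ch, kernel=1)
        self.bn_proj = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        outs = [self.bn1(self.conv1(x)).relu()]
        for d, conv, bn in zip(self.dilations, self.branches, self.branch_bns):
            if min(H, W) <= d:
                if (d, H, W) not in self._warned:
                    warnings.warn(f"ASPP: dropping dilation {d} for {H}x{W} input")
                    self._warned.add((d, H, W))
                continue
            outs.append(bn(conv(x)).relu())
        pooled = self.pool_fc(global_avg_pool(x)).relu()          # (B, out)
        ones = Tensor(x.data[:, :1] * 0 + 1.0)                    # (B,1,H,W) broadcast helper
        outs.append(pooled.reshape(B, -1, 1, 1) * ones)
        h = concat(outs, axis=1)
        if h.shape[1] < self.project.in_ch:
            # dropped dilation branches contribute zero channels
            deficit = self.project.in_ch - h.shape[1]
            h = concat([h, Tensor(np.zeros((B, deficit, H, W), dtype=h.data.dtype))], axis=1)
        return self.bn_proj(self.project(h)).relu()


class Stem(nn.Module):
    """3x3 convolution + BN + ReLU, stride 1."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel=3)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class EncoderBlock(nn.Module):
    """SE-ResNeXt followed by 2x2 max pooling; exposes the pre-pool feature."""

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        self.block = SEResNeXtBlock(cfg)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        f = self.block(x)
        return f, maxpool2x(f)


class DecoderBlock(nn.Module):
    """SE-ResNeXt applied to an (already fused) decoder input."""

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        self.block = SEResNeXtBlock(cfg)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


@dataclass(frozen=True)
class BackboneConfig:
    """Channel plan of the shared encoder/decoder body."""

    stem_channels: int = 16
    encoder_channels: tuple[int, int, int] = (32, 64, 128)
    bridge_channels: int = 128
    cardinality: int = 8
    se_reduction: int = 4
    aspp_dilations: tuple[int, ...] = (3, 6, 9)

    def level_cfg(self, cin: int, cout: int) -> BlockConfig:
        return BlockConfig(cin, cout, self.cardinality, self.se_reduction,
                           self.aspp_dilations)
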
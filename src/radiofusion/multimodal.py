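"""Intra- and inter-modality attention fusion for the classifier.

*Intra fusion* aligns each of the three segmentation decoder features with
the initial classification feature map (all resampled to the coarsest grid)
and runs a MultiRes-style chain of three 3x3 convolution stages in which
every stage re-injects the initial fusion — so shallow information survives
depth.

*Inter fusion* concatenates the three intra-fused maps, the classification
map and the gene embedding (tiled over the spatial grid) into a multimodal
stack, projects it to C channels, derives Query/Key/Value with three
single-channel 3-tap convolutions oriented along the channel, height and
width axes of the (C,H,W) volume, and applies non-local attention:
``A = softmax(Query^T Key)`` column-normalized so each output position mixes
a convex combination of input positions, then ``Value @ A`` is added back to
the projected stack (residual sum).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .nn import avg_pool_to


class WiringError(ValueError):
    pass


class ResourceError(RuntimeError):
    pass


class ConvStage(nn.Module):
    """3x3 conv (+ optional BN) + ReLU."""

    def __init__(self, ch: int, use_norm: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(ch, ch, kernel=3)
        self.bn = nn.BatchNorm2d(ch) if use_norm else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        if self.bn is not None:
            h = self.bn(h)
        return h.relu()


class IntraFusion(nn.Module):
    """Fuse three segmentation features with the classification feature.

    Each segmentation feature is average-pooled to the classification grid,
    1x1-projected to the classification width, then chained:

        F_SC^i   = conv3(F_S^i') + conv3(F_Ccls)
        stage1   = conv(F_SC^i)
        stage2   = conv(stage1 + F_SC^i)
        F_Intra^i = conv(stage2 + F_SC^i)
    """

    def __init__(self, seg_channels: tuple[int, int, int], cls_channels: int,
                 use_norm: bool = True):
        super().__init__()
        self.n_levels = len(seg_channels)
        self.cls_channels = cls_channels
        self.proj = nn.ModuleList([nn.Conv2d(c, cls_channels, kernel=1)
                                   for c in seg_channels])
        self.seg_conv = nn.ModuleList([ConvStage(cls_channels, use_norm)
                                       for _ in seg_channels])
        self.cls_conv = nn.ModuleList([ConvStage(cls_channels, use_norm)
                                       for _ in seg_channels])
        # three successive conv stages per level
        self.chain = nn.ModuleList([
            nn.ModuleList([ConvStage(cls_channels, use_norm) for _ in range(3)])
            for _ in seg_channels])

    def forward(self, f_seg: list[Tensor], f_cls: Tensor) -> list[Tensor]:
        if len(f_seg) != self.n_levels:
            raise WiringError(f"expected {self.n_levels} segmentation features, "
                              f"got {len(f_seg)}")
        B, C, H, W = f_cls.shape
        outs = []
        for i, fs in enumerate(f_seg):
            fs_small = avg_pool_to(fs, (H, W))
            fs_proj = self.proj[i](fs_small)
            f_sc = self.seg_conv[i](fs_proj) + self.cls_conv[i](f_cls)
            h = self.chain[i][0](f_sc)
            h = self.chain[i][1](h + f_sc)
            h = self.chain[i][2](h + f_sc)
            outs.append(h)
        return outs


class AxisConv3(nn.Module):
    """Single-channel 3-tap convolution along one axis of the (C,H,W) volume.

    ``axis`` is 1 (channel), 2 (height) or 3 (width) of the NCHW tensor;
    zero padding preserves shape.  This realizes 3x1x1 / 1x3x1 / 1x1x3
    kernels over the feature volume.
    """

    def __init__(self, axis: int):
        super().__init__()
        if axis not in (1, 2, 3):
            raise ValueError("axis must be 1, 2 or 3")
        self.axis = axis
        rng = nn._init_rng()
        self.taps = nn.Parameter(np.array([0.0, 1.0, 0.0]) + rng.normal(0, 0.1, 3))
        self.bias = nn.Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        w = self.taps
        out = (x.shift(self.axis, 1) * w[0] + x * w[1] + x.shift(self.axis, -1) * w[2])
        return out + self.bias.reshape(1)


class Conv2dQKV(nn.Module):
    """Conventional 2-D (3x1)/(1x3)/(1x1) alternative for Q/K/V (config flag)."""

    KERNELS = {"q": (3, 1), "k": (1, 3), "v": (1, 1)}

    def __init__(self, ch: int, which: str):
        super().__init__()
        kh, kw = self.KERNELS[which]
        # implemented as two chained square convs would change semantics; use
        # a 3-tap axis conv for the anisotropic kernels instead
        self.inner = AxisConv3(2 if which == "q" else 3) if which != "v" else None
        self.pointwise = nn.Conv2d(ch, ch, kernel=1)

    def forward(self, x: Tensor) -> Tensor:
        h = x if self.inner is None else self.inner(x)
        return self.pointwise(h)


class InterFusion(nn.Module):
    """Multimodal non-local attention fusion (image features + gene embedding)."""

    def __init__(self, cls_channels: int, n_intra: int, gene_dim: int,
                 attention_size_cap: int = 4096, qkv_mode: str = "triaxis",
                 use_norm: bool = True):
        super().__init__()
        self.cls_channels = cls_channels
        self.gene_dim = gene_dim
        self.attention_size_cap = attention_size_cap
        total = cls_channels * (n_intra + 1) + gene_dim
        self.stack_proj = nn.Conv2d(total, cls_channels, kernel=1)
        if qkv_mode == "triaxis":
            self.q_conv = AxisConv3(2)   # 1x3x1 -> along H
            self.k_conv = AxisConv3(1)   # 3x1x1 -> along C
            self.v_conv = AxisConv3(3)   # 1x1x3 -> along W
        elif qkv_mode == "conv2d":
            self.q_conv = Conv2dQKV(cls_channels, "q")
            self.k_conv = Conv2dQKV(cls_channels, "k")
            self.v_conv = Conv2dQKV(cls_channels, "v")
        else:
            raise ValueError("qkv_mode must be 'triaxis' or 'conv2d'")
        self.q_bn = nn.BatchNorm2d(cls_channels) if use_norm else None
        self.k_bn = nn.BatchNorm2d(cls_channels) if use_norm else None
        self.v_bn = nn.BatchNorm2d(cls_channels) if use_norm else None

    def _qkv(self, conv, bn, m: Tensor) -> Tensor:
        h = conv(m)
        if bn is not None:
            h = bn(h)
        return h.relu()

    def attention(self, query: Tensor, key: Tensor) -> Tensor:
        """Column-stochastic attention matrix A = softmax(Q^T K) (per batch)."""
        B, C, H, W = query.shape
        q = query.reshape(B, C, H * W)
        k = key.reshape(B, C, H * W)
        scores = q.transpose(0, 2, 1) @ k          # (B, HW, HW)
        return scores.softmax(axis=1)              # columns sum to 1

    def forward(self, f_intra: list[Tensor], f_cls: Tensor, genes: Tensor) -> Tensor:
        B, C, H, W = f_cls.shape
        if H * W > self.attention_size_cap:
            raise ResourceError(
                f"attention over {H * W} positions exceeds cap "
                f"{self.attention_size_cap}; pool the features first")
        if not np.isfinite(genes.data).all():
            raise ValueError("gene embedding contains non-finite values")
        ones = Tensor(np.ones((B, 1, H, W), dtype=f_cls.data.dtype))
        g_map = genes.reshape(B, self.gene_dim, 1, 1) * ones     # tile over HxW
        m_c = concat(list(f_intra) + [f_cls, g_map], axis=1)
        m_proj = self.stack_proj(m_c)                            # (B, C, H, W)
        query = self._qkv(self.q_conv, self.q_bn, m_proj)
        key = self._qkv(self.k_conv, self.k_bn, m_proj)
        value = self._qkv(self.v_conv, self.v_bn, m_proj)
        a = self.attention(query, key)                           # (B, HW, HW)
        attended = (value.reshape(B, C, H * W) @ a).reshape(B, C, H, W)
        return m_proj + attended


class ClassifierHead(nn.Module):
    """Global average pool -> fully connected -> mutation logit."""

    def __init__(self, ch: int):
        super().__init__()
        self.fc = nn.Linear(ch, 1)

    def forward(self, f_inter: Tensor) -> Tensor:
        pooled = f_inter.mean(axis=(2, 3))
        return self.fc(pooled).reshape(-1)   # logits

    def probability(self, f_inter: Tensor) -> Tensor:
        return self.forward(f_inter).sigmoid()
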
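"""Attention-guided aggregation of a low-level encoder feature with an
upsampled high-level decoder feature (the segmentation network's skip path).

The fusion proceeds in five steps:

1. bilinear-upsample the high-level map to the low-level grid and
   channel-concatenate:  ``F_C = [F_low, up(F_high)]``;
2. channel guidance: a shared one-hidden-layer MLP applied to the global
   average pool (``F_AM``) and the global max pool (``F_MM``) of ``F_C``;
   their sum through a sigmoid gives per-channel coefficients ``W_global``;
3. residual attention gates: ``W_high = sigmoid(up(F_high) + F_AM[high part])``
   and ``W_low = sigmoid(F_low + F_MM[low part])``, the guidance vectors
   broadcast per channel over the spatial grid.  The split of each guidance
   vector follows the concatenation order of step 1 — the first C_low entries
   belong to the low stream, the last C_high to the high stream;
4. gated residuals ``F*_att = F* * W* + F*`` (so each gated feature keeps the
   sign of its input with magnitude in [|x|, 2|x|]);
5. ``F_out = Conv1x1(W_global * [F_low_att, F_high_att])``.

``gate_mode='channel'`` replaces the spatially resolved gate maps of step 3
with per-channel scalar gates computed from globally pooled features — an
alternative reading of the gating, kept behind a flag.
"""

from __future__ import annotations

from . import nn
from .autograd import Tensor, concat, upsample2x
from .nn import global_avg_pool, global_max_pool


class SharedMLP(nn.Module):
    """One-hidden-layer MLP applied with identical weights to both pooled vectors."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())


class ChannelGuidance(nn.Module):
    """Produce (W_global, F_AM, F_MM) from a concatenated feature map."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        self.channels = channels
        self.mlp = SharedMLP(channels, reduction)

    def forward(self, f_c: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if f_c.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {f_c.shape[1]}")
        f_am = self.mlp(global_avg_pool(f_c))   # from GAP
        f_mm = self.mlp(global_max_pool(f_c))   # from GMP
        w_global = (f_am + f_mm).sigmoid()
        return w_global, f_am, f_mm


class AttentionFusion(nn.Module):
    """Fuse ``F_low`` (C_low, H, W) with ``F_high`` (C_high, H/2, W/2 or H, W)."""

    def __init__(self, low_channels: int, high_channels: int, out_channels: int,
                 reduction: int = 4, gate_mode: str = "map",
                 project_high_to: int | None = None):
        super().__init__()
        if gate_mode not in ("map", "channel"):
            raise ValueError("gate_mode must be 'map' or 'channel'")
        self.low_channels = low_channels
        self.gate_mode = gate_mode
        if project_high_to is not None and project_high_to != high_channels:
            self.high_proj = nn.Conv2d(high_channels, project_high_to, kernel=1)
            high_channels = project_high_to
        else:
            self.high_proj = None
        self.high_channels = high_channels
        cat_ch = low_channels + high_channels
        self.guidance = ChannelGuidance(cat_ch, reduction)
        self.project = nn.Conv2d(cat_ch, out_channels, kernel=1)
        self.out_channels = out_channels

    def forward(self, f_low: Tensor, f_high: Tensor) -> Tensor:
        B, c_low, H, W = f_low.shape
        if c_low != self.low_channels:
            raise ValueError(f"F_low has {c_low} channels, expected {self.low_channels}")
        if f_high.shape[2:] == (H // 2, W // 2):
            f_high_up = upsample2x(f_high)
        elif f_high.shape[2:] == (H, W):
            f_high_up = f_high
        else:
            raise ValueError(f"incompatible spatial sizes: F_low {H}x{W}, "
                             f"F_high {f_high.shape[2]}x{f_high.shape[3]}")
        if self.high_proj is not None:
            f_high_up = self.high_proj(f_high_up)
        c_high = f_high_up.shape[1]
        if c_high != self.high_channels:
            raise ValueError(f"F_high has {c_high} channels, expected {self.high_channels}")

        f_cat = concat([f_low, f_high_up], axis=1)
        w_global, f_am, f_mm = self.guidance(f_cat)

        g_high = f_am[:, c_low:].reshape(B, c_high, 1, 1)   # high part of F_AM
        g_low = f_mm[:, :c_low].reshape(B, c_low, 1, 1)     # low part of F_MM
        if self.gate_mode == "map":
            w_high = (f_high_up + g_high).sigmoid()
            w_low = (f_low + g_low).sigmoid()
        else:
            w_high = (global_avg_pool(f_high_up).reshape(B, c_high, 1, 1) + g_high).sigmoid()
            w_low = (global_avg_pool(f_low).reshape(B, c_low, 1, 1) + g_low).sigmoid()

        f_high_att = f_high_up * w_high + f_high_up
        f_low_att = f_low * w_low + f_low
        fused = concat([f_low_att, f_high_att], axis=1)
        fused = fused * w_global.reshape(B, c_low + c_high, 1, 1)
        return self.project(fused)


class ConcatFusion(nn.Module):
    """Plain upsample-concat-project skip fusion (ablation drop-in)."""

    def __init__(self, low_channels: int, high_channels: int, out_channels: int, **_):
        super().__init__()
        self.project = nn.Conv2d(low_channels + high_channels, out_channels, kernel=1)
        self.out_channels = out_channels

    def forward(self, f_low: Tensor, f_high: Tensor) -> Tensor:
        H, W = f_low.shape[2:]
        if f_high.shape[2:] == (H // 2, W // 2):
            f_high = upsample2x(f_high)
        return self.project(concat([f_low, f_high], axis=1))
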
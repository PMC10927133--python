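"""Intra/inter fusion: shape contracts, loop oracles, attention stochasticity."""

import numpy as np
import pytest

from radiofusion import nn
from radiofusion.autograd import Tensor
from radiofusion.multimodal import (AxisConv3, ClassifierHead, InterFusion,
                                    IntraFusion, ResourceError, WiringError)

from conftest import identity_conv3, zero_linear


def _t(shape, seed=0, scale=1.0):
    return Tensor((np.random.default_rng(seed).normal(size=shape) * scale).astype(np.float32))


def test_intra_shape_contract():
    nn.manual_seed(0)
    intra = IntraFusion(seg_channels=(16, 32, 64), cls_channels=64)
    intra.eval()
    f_seg = [_t((2, 16, 32, 32), 1), _t((2, 32, 16, 16), 2), _t((2, 64, 8, 8), 3)]
    f_cls = _t((2, 64, 8, 8), 4)
    outs = intra(f_seg, f_cls)
    assert len(outs) == 3
    for o in outs:
        assert o.shape == (2, 64, 8, 8)
    with pytest.raises(WiringError):
        intra(f_seg[:2], f_cls)


def test_intra_zero_convs_give_zero_outputs():
    nn.manual_seed(1)
    intra = IntraFusion(seg_channels=(4, 4), cls_channels=4, use_norm=False)
    for mod in intra.modules():
        if isinstance(mod, nn.Conv2d):
            mod.weight.data = np.zeros_like(mod.weight.data)
            if mod.bias is not None:
                mod.bias.data = np.zeros_like(mod.bias.data)
    outs = intra([_t((1, 4, 8, 8), 1), _t((1, 4, 8, 8), 2)], _t((1, 4, 8, 8), 3))
    for o in outs:
        np.testing.assert_allclose(o.data, 0.0, atol=1e-8)


def test_intra_stage_recurrence_matches_loop_oracle():
    """Identity convs, positive inputs: stages reduce to h -> h + F_SC."""
    nn.manual_seed(2)
    intra = IntraFusion(seg_channels=(1,), cls_channels=1, use_norm=False)
    identity_conv3(intra.proj[0])
    identity_conv3(intra.seg_conv[0].conv)
    identity_conv3(intra.cls_conv[0].conv)
    for stage in intra.chain[0]:
        identity_conv3(stage.conv)
    fs = np.abs(np.random.default_rng(2).normal(size=(1, 1, 2, 2))).astype(np.float32)
    fc = np.abs(np.random.default_rng(3).normal(size=(1, 1, 2, 2))).astype(np.float32)
    out = intra([Tensor(fs)], Tensor(fc))[0].data
    # oracle: elementwise transcription over the 4 pixels
    f_sc = fs + fc                       # identity convs + ReLU on positives
    h = f_sc.copy()
    for _ in range(2):
        h = h + f_sc
    np.testing.assert_allclose(out, h, atol=1e-6)


def test_axis_conv_runs_along_named_axis():
    nn.manual_seed(3)
    conv = AxisConv3(axis=2)   # along H
    conv.taps.data = np.array([1.0, 0.0, 0.0], dtype=np.float32)  # pure +1 shift
    conv.bias.data = np.zeros(1, dtype=np.float32)
    x = np.zeros((1, 1, 4, 4), dtype=np.float32)
    x[0, 0, 1, :] = 1.0
    out = conv(Tensor(x)).data
    assert out[0, 0, 2].sum() == 4.0 and out[0, 0, 1].sum() == 0.0


def test_attention_columns_are_probability_vectors():
    nn.manual_seed(4)
    inter = InterFusion(cls_channels=8, n_intra=3, gene_dim=4)
    for seed, hw in ((5, 4), (6, 8)):
        q = _t((2, 8, hw, hw), seed)
        k = _t((2, 8, hw, hw), seed + 10)
        a = inter.attention(q, k).data
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)
        assert (a >= 0).all()


def test_constant_query_key_yields_uniform_attention_and_value_mean():
    nn.manual_seed(5)
    inter = InterFusion(cls_channels=4, n_intra=3, gene_dim=4)
    H = W = 4
    q = Tensor(np.full((1, 4, H, W), 0.3, dtype=np.float32))
    k = Tensor(np.full((1, 4, H, W), -1.2, dtype=np.float32))
    a = inter.attention(q, k).data
    np.testing.assert_allclose(a, 1.0 / (H * W), atol=1e-6)
    v = np.random.default_rng(5).normal(size=(1, 4, H, W)).astype(np.float32)
    attended = (v.reshape(1, 4, H * W) @ a).reshape(1, 4, H, W)
    expected = np.broadcast_to(v.mean(axis=(2, 3), keepdims=True), v.shape)
    np.testing.assert_allclose(attended, expected, atol=1e-5)


def test_inter_shape_contract_and_resource_cap():
    nn.manual_seed(6)
    inter = InterFusion(cls_channels=64, n_intra=3, gene_dim=32)
    inter.eval()
    f_intra = [_t((1, 64, 8, 8), s) for s in (1, 2, 3)]
    f_cls = _t((1, 64, 8, 8), 4)
    g = _t((1, 32), 5)
    out = inter(f_intra, f_cls, g)
    assert out.shape == (1, 64, 8, 8)
    capped = InterFusion(cls_channels=4, n_intra=3, gene_dim=4, attention_size_cap=16)
    with pytest.raises(ResourceError, match="pool"):
        capped([_t((1, 4, 8, 8), s) for s in (1, 2, 3)], _t((1, 4, 8, 8), 4), _t((1, 4), 5))


def test_inter_matches_nested_loop_oracle_on_tiny_volume():
    """Full transcription of stack-projection + tri-axis QKV + attention."""
    nn.manual_seed(7)
    C, H, W = 3, 2, 2
    inter = InterFusion(cls_channels=C, n_intra=2, gene_dim=2, use_norm=False)
    inter.eval()
    rng = np.random.default_rng(7)
    f_intra = [Tensor(rng.normal(size=(1, C, H, W)).astype(np.float32)) for _ in range(2)]
    f_cls = Tensor(rng.normal(size=(1, C, H, W)).astype(np.float32))
    g = Tensor(rng.normal(size=(1, 2)).astype(np.float32))
    out = inter(f_intra, f_cls, g).data

    # oracle -----------------------------------------------------------
    stack = np.concatenate([t.data for t in f_intra] + [f_cls.data], axis=1)
    g_map = np.repeat(np.repeat(g.data[:, :, None, None], H, 2), W, 3)
    m_c = np.concatenate([stack, g_map], axis=1)
    pw = inter.stack_proj.weight.data[:, :, 0, 0]
    pb = inter.stack_proj.bias.data
    m = np.einsum("oc,bchw->bohw", pw, m_c) + pb[None, :, None, None]

    def axis_conv(x, taps, bias, axis):
        out = np.zeros_like(x)
        for c in range(x.shape[1]):
            for h in range(x.shape[2]):
                for w in range(x.shape[3]):
                    acc = taps[1] * x[0, c, h, w]
                    idx = [0, c, h, w]
                    idx[axis] -= 1
                    if idx[axis] >= 0:
                        acc += taps[0] * x[tuple(idx)]
                    idx[axis] += 2
                    if idx[axis] < x.shape[axis]:
                        acc += taps[2] * x[tuple(idx)]
                    out[0, c, h, w] = acc + bias[0]
        return np.maximum(out, 0.0)

    q = axis_conv(m, inter.q_conv.taps.data, inter.q_conv.bias.data, 2)
    k = axis_conv(m, inter.k_conv.taps.data, inter.k_conv.bias.data, 1)
    v = axis_conv(m, inter.v_conv.taps.data, inter.v_conv.bias.data, 3)
    qf, kf, vf = (t.reshape(C, H * W) for t in (q[0], k[0], v[0]))
    scores = qf.T @ kf
    e = np.exp(scores - scores.max(axis=0, keepdims=True))
    a = e / e.sum(axis=0, keepdims=True)
    attended = (vf @ a).reshape(C, H, W)
    ref = m[0] + attended
    np.testing.assert_allclose(out[0], ref, atol=1e-5)


def test_gene_branch_receives_gradient():
    """Perturbing G must change the fused output (no dead gene path)."""
    nn.manual_seed(8)
    inter = InterFusion(cls_channels=4, n_intra=3, gene_dim=4)
    f_intra = [_t((1, 4, 4, 4), s) for s in (1, 2, 3)]
    f_cls = _t((1, 4, 4, 4), 4)
    g = Tensor(np.random.default_rng(9).normal(size=(1, 4)).astype(np.float32),
               requires_grad=True)
    out = inter(f_intra, f_cls, g)
    out.sum().backward()
    assert g.grad is not None
    assert np.abs(g.grad).max() > 0


def test_head_zero_weights_give_half_probability():
    nn.manual_seed(9)
    head = ClassifierHead(6)
    zero_linear(head.fc)
    f = _t((3, 6, 4, 4), 10)
    p = head.probability(f).data
    np.testing.assert_allclose(p, 0.5, atol=1e-7)
    p2 = head.probability(f).data
    np.testing.assert_array_equal(p, p2)
    nn.manual_seed(10)
    head2 = ClassifierHead(6)
    assert ((head2.probability(f).data > 0) & (head2.probability(f).data < 1)).all()
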
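import numpy as np
import pytest

from radiofusion import nn
from radiofusion.backbone import BackboneConfig
from radiofusion.phantom import PhantomConfig, generate_cohort

TINY_BACKBONE = BackboneConfig(stem_channels=4, encoder_channels=(8, 8, 16),
                               bridge_channels=16, cardinality=2, se_reduction=2)


@pytest.fixture
def tiny_backbone() -> BackboneConfig:
    return TINY_BACKBONE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """80-sample 16x16 cohort with a strong gene effect (shared across tests)."""
    cfg = PhantomConfig(n_samples=80, image_size=16, lesion_radius_range=(3, 6),
                        gene_effect=2.0, n_genes=120, n_informative=10, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(autouse=True)
def _seed_init():
    nn.manual_seed(0)


def zero_linear(layer):
    layer.weight.data = np.zeros_like(layer.weight.data)
    if layer.bias is not None:
        layer.bias.data = np.zeros_like(layer.bias.data)


def identity_linear(layer):
    n = layer.weight.data.shape[0]
    layer.weight.data = np.eye(n, layer.weight.data.shape[1], dtype=np.float32)
    if layer.bias is not None:
        layer.bias.data = np.zeros_like(layer.bias.data)


def identity_conv3(conv):
    """Set a 3x3 conv to the per-channel identity (center tap 1)."""
    w = np.zeros_like(conv.weight.data)
    n = min(w.shape[0], w.shape[1])
    for i in range(n):
        w[i, i, w.shape[2] // 2, w.shape[3] // 2] = 1.0
    conv.weight.data = w
    if conv.bias is not None:
        conv.bias.data = np.zeros_like(conv.bias.data)
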
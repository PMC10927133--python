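"""Synthetic radiogenomics phantom cohort.

Generates paired 2-D grayscale lesion images, per-pixel binary masks, binary
mutation labels and gene-expression vectors, with a configurable
labeled/unlabeled split, so the segmentation and semi-supervised
classification networks can be exercised without any external download.

The cohort emulates the structure of a CT + RNA-seq radiogenomics study:

* each image is a textured-noise background with one elliptical lesion;
* the lesion's mean intensity and texture variance depend on the class
  (``texture_shift`` controls the image-side separability — with 0 the two
  classes are image-indistinguishable);
* expression vectors have ``n_informative`` genes (columns 0..n_informative-1)
  whose class-conditional means differ by ``gene_effect`` standard deviations;
  all remaining genes are label-independent standard normal noise;
* 30% of the training samples carry labels by default, mirroring a
  semi-supervised protocol with scarce annotation.

Determinism: every sample is rendered from its own counter-based random
stream ``default_rng([seed, index])``, so a cohort is a pure function of
(config, seed) and invariant to generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _sk_ellipse


class ConfigurationError(ValueError):
    """Raised when a phantom configuration violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when a lesion cannot be placed inside the frame."""


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 200
    image_size: int = 64
    lesion_radius_range: tuple[int, int] = (6, 14)
    lesion_contrast: float = 0.5
    background_noise_sd: float = 0.08
    texture_shift: float = 0.3
    n_genes: int = 500
    n_informative: int = 20
    gene_effect: float = 1.0
    mutation_fraction: float = 0.4
    labeled_fraction: float = 0.30
    test_fraction: float = 0.20   # 4:1 train/test split
    seed: int = 0

    def validate(self) -> "PhantomConfig":
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.image_size < 8 or self.image_size % 8:
            raise ConfigurationError("image_size must be a positive multiple of 8")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError("lesion_radius_range must satisfy 0 < min <= max")
        if hi >= self.image_size / 2:
            raise ConfigurationError("lesion_radius_range.max must be < image_size/2")
        if not 0 < self.mutation_fraction < 1:
            raise ConfigurationError("mutation_fraction must lie in (0, 1)")
        if not 0 < self.labeled_fraction <= 1:
            raise ConfigurationError("labeled_fraction must lie in (0, 1]")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        if self.n_informative > self.n_genes:
            raise ConfigurationError("n_informative must be <= n_genes")
        if self.background_noise_sd < 0 or self.lesion_contrast < 0 or self.gene_effect < 0:
            raise ConfigurationError("noise/contrast/effect parameters must be non-negative")
        return self


@dataclass
class PhantomSample:
    """One study subject: image X, mask Y, label Z, expression vector."""

    image: np.ndarray          # (H, W) float32 in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    label: int                 # 0 = wildtype, 1 = mutation
    genes: np.ndarray          # (n_genes,) float32
    is_labeled: bool


@dataclass
class PhantomCohort:
    samples: list[PhantomSample]
    split: dict[str, np.ndarray] = field(default_factory=dict)
    config: PhantomConfig | None = None

    def __len__(self):
        return len(self.samples)

    def images(self, idx) -> np.ndarray:
        return np.stack([self.samples[i].image for i in idx])[:, None]  # (B,1,H,W)

    def masks(self, idx) -> np.ndarray:
        return np.stack([self.samples[i].mask for i in idx])[:, None].astype(np.float32)

    def labels(self, idx) -> np.ndarray:
        return np.array([self.samples[i].label for i in idx], dtype=np.float32)

    def genes(self, idx) -> np.ndarray:
        return np.stack([self.samples[i].genes for i in idx])

    def expression_matrix(self) -> np.ndarray:
        return np.stack([s.genes for s in self.samples])


# ---------------------------------------------------------------------------

_BACKGROUND_LEVEL = 0.15


def render_sample(label: int, config: PhantomConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion image and its mask.

    The mask is a filled random ellipse; the image is background noise plus
    ``lesion_contrast`` inside the mask plus a class-conditional texture term
    (mean shift ``0.5*texture_shift`` and extra variance for class 1),
    clipped to [0, 1].
    """
    n = config.image_size
    lo, hi = config.lesion_radius_range
    for _ in range(100):
        ry = rng.uniform(lo, hi)
        rx = rng.uniform(lo, hi)
        rot = rng.uniform(0, np.pi)
        margin = max(ry, rx) + 1
        if n - margin <= margin:
            continue
        cy = rng.uniform(margin, n - margin)
        cx = rng.uniform(margin, n - margin)
        rr, cc = _sk_ellipse(cy, cx, ry, rx, shape=(n, n), rotation=rot)
        if rr.size:
            break
    else:
        raise GenerationError("lesion does not fit in frame after 100 placement attempts")
    mask = np.zeros((n, n), dtype=np.uint8)
    mask[rr, cc] = 1
    image = np.full((n, n), _BACKGROUND_LEVEL, dtype=np.float64)
    if config.background_noise_sd > 0:
        image += rng.normal(0.0, config.background_noise_sd, size=(n, n))
    image += config.lesion_contrast * mask
    if config.texture_shift > 0:
        texture_sd = 0.25 * config.texture_shift * label
        texture_mu = 0.5 * config.texture_shift * label
        texture = rng.normal(texture_mu, texture_sd if texture_sd > 0 else 1e-12, size=(n, n))
        image += texture * mask
    return np.clip(image, 0.0, 1.0).astype(np.float32), mask


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _render_one(index: int, config: PhantomConfig) -> PhantomSample:
    rng = _sample_rng(config.seed, index)
    label = int(rng.random() < config.mutation_fraction)
    image, mask = render_sample(label, config, rng)
    genes = rng.standard_normal(config.n_genes)
    genes[: config.n_informative] += label * config.gene_effect
    return PhantomSample(image=image, mask=mask, label=label,
                         genes=genes.astype(np.float32), is_labeled=False)


def _stratified_pick(indices: np.ndarray, labels: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Pick ~fraction of ``indices`` preserving class prevalence."""
    chosen = []
    for cls in (0, 1):
        pool = indices[labels[indices] == cls]
        k = int(round(fraction * len(pool)))
        if len(pool):
            k = min(max(k, 1 if fraction > 0 else 0), len(pool))
            chosen.append(rng.permutation(pool)[:k])
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate a full phantom cohort with train/test and labeled splits.

    Splits are stratified by class: the test set holds ``test_fraction`` of
    each class, and within the training set ``labeled_fraction`` of each
    class is labeled.
    """
    config.validate()
    samples = [_render_one(i, config) for i in range(config.n_samples)]
    labels = np.array([s.label for s in samples])
    split_rng = np.random.default_rng([config.seed, 0xC0FFEE])
    all_idx = np.arange(config.n_samples)
    test = _stratified_pick(all_idx, labels, config.test_fraction, split_rng)
    train = np.setdiff1d(all_idx, test)
    train_labeled = _stratified_pick(train, labels, config.labeled_fraction, split_rng)
    train_unlabeled = np.setdiff1d(train, train_labeled)
    for i in train_labeled:
        samples[i].is_labeled = True
    for i in test:
        samples[i].is_labeled = True  # test labels exist for evaluation
    return PhantomCohort(samples=samples,
                         split={"train_labeled": train_labeled,
                                "train_unlabeled": train_unlabeled,
                                "test": test},
                         config=config)


def config_as_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["lesion_radius_range"] = list(d["lesion_radius_range"])
    return d
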
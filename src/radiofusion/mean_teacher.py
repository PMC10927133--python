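"""Student/Teacher classification model and the semi-supervised trainer.

The Student re-uses the segmentation network body (stem, encoders, bridge,
attention-fused decoders) — its weights are copied from a segmentation
checkpoint at build time and fine-tuned — and adds: a classification stem
that pools the finest decoder feature down to the coarse grid, the
intra/inter attention fusion, the gene MLP and the classification head.

The Teacher is a structurally identical copy whose weights track the
exponential moving average of the Student's:

    w_t <- alpha * w_t + (1 - alpha) * w_s        (every optimizer step)

Training loss per batch:

    BCE(student(x_L, g_L), z_L)
      + w(t) * MSE(student_prob(x_U + n1, g_U), teacher_prob(x_U + n2, g_U))

where n1, n2 are independent Gaussian perturbations of the unlabeled images
and w(t) ramps from 0 to ``consistency_weight_max`` as
``exp(-5 (1 - t/T)^2)`` over the first ``rampup_epochs`` epochs (the
canonical Mean-Teacher sigmoid-shaped ramp).  The final Student makes the
predictions.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, bce_with_logits, no_grad
from .backbone import BackboneConfig
from .genes import GeneMLP, GeneScreen
from .metrics import auc_trapezoid
from .multimodal import ClassifierHead, ConvStage, InterFusion, IntraFusion
from .phantom import PhantomCohort
from .segnet import SegModel


@dataclass
class ClassifierConfig:
    cls_channels: int = 32
    gene_hidden: int = 64
    gene_embed: int = 32
    qkv_mode: str = "triaxis"
    use_genes: bool = True


class StudentModel(nn.Module):
    """Segmentation-body-backed multimodal classifier."""

    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 cls_cfg: ClassifierConfig | None = None, gene_k: int = 115,
                 fusion: str = "attention"):
        super().__init__()
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.cls_cfg = cls_cfg or ClassifierConfig()
        self.gene_k = gene_k
        self.body = SegModel(self.backbone_cfg, fusion=fusion)
        c1, c2, c3 = self.backbone_cfg.encoder_channels
        cc = self.cls_cfg.cls_channels
        self.cls_proj = nn.Conv2d(c1, cc, kernel=3)   # applied after pooling d1 to H/8
        self.cls_stage = ConvStage(cc)
        self.intra = IntraFusion(seg_channels=(c3, c2, c1), cls_channels=cc)
        self.gene_mlp = GeneMLP(gene_k, self.cls_cfg.gene_hidden, self.cls_cfg.gene_embed)
        self.inter = InterFusion(cc, n_intra=3, gene_dim=self.cls_cfg.gene_embed,
                                 qkv_mode=self.cls_cfg.qkv_mode)
        self.head = ClassifierHead(cc)

    def forward_logits(self, images: Tensor, genes: Tensor) -> Tensor:
        B, _, H, W = images.shape
        _, f_seg = self.body.forward_features(images)     # [d3@H/4, d2@H/2, d1@H]
        d1 = f_seg[2]
        coarse = nn.avg_pool_to(d1, (H // 8, W // 8))
        f_cls = self.cls_stage(self.cls_proj(coarse))
        f_intra = self.intra(f_seg, f_cls)
        if self.cls_cfg.use_genes:
            g = self.gene_mlp(genes)
        else:
            g = Tensor(np.zeros((B, self.cls_cfg.gene_embed), dtype=np.float32))
        f_inter = self.inter(f_intra, f_cls, g)
        return self.head(f_inter)

    def forward(self, images: Tensor, genes: Tensor) -> Tensor:
        return self.forward_logits(images, genes).sigmoid()


class CheckpointError(ValueError):
    pass


def build_student(seg_state: dict[str, np.ndarray],
                  backbone_cfg: BackboneConfig | None = None,
                  cls_cfg: ClassifierConfig | None = None,
                  gene_k: int = 115, fusion: str = "attention") -> StudentModel:
    """Construct a Student whose body weights equal the segmentation checkpoint."""
    model = StudentModel(backbone_cfg, cls_cfg, gene_k, fusion=fusion)
    try:
        model.body.load_state_dict(seg_state)
    except (KeyError, ValueError) as exc:
        raise CheckpointError(f"segmentation checkpoint incompatible: {exc}") from exc
    return model


@dataclass
class TeacherStudentPair:
    student: StudentModel
    teacher: StudentModel
    alpha: float = 0.99
    step: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.teacher.set_requires_grad(False)
        self.teacher.eval()


def make_pair(student: StudentModel, alpha: float = 0.99) -> TeacherStudentPair:
    teacher = copy.deepcopy(student)
    return TeacherStudentPair(student=student, teacher=teacher, alpha=alpha)


def ema_update(pair: TeacherStudentPair) -> TeacherStudentPair:
    """w_t <- alpha*w_t + (1-alpha)*w_s for every parameter and BN statistic."""
    a = pair.alpha
    s_state = pair.student.state_dict()
    t_params = dict(pair.teacher.named_parameters())
    for name, arr in s_state.items():
        if name in t_params:
            t = t_params[name]
            if t.data.shape != arr.shape:
                raise ValueError(f"wiring error: shape mismatch for {name}")
            t.data = a * t.data + (1 - a) * arr
    # buffers (running statistics) follow the same average
    t_buf_holder = pair.teacher
    for name, arr in s_state.items():
        if name not in t_params:
            _ema_buffer(t_buf_holder, name.split("."), a, arr)
    pair.step += 1
    return pair


def _ema_buffer(module: nn.Module, path: list[str], a: float, arr: np.ndarray):
    if len(path) == 1:
        old = module._buffers[path[0]]
        module._set_buffer(path[0], (a * old + (1 - a) * arr).astype(old.dtype))
    else:
        _ema_buffer(module._modules[path[0]], path[1:], a, arr)


@dataclass
class SemiTrainConfig:
    epochs: int = 20
    learning_rate: float = 0.001
    batch_size: int = 16
    alpha: float = 0.99
    consistency_weight_max: float = 1.0
    rampup_epochs: int = 5
    noise_sd: float = 0.05
    val_fraction: float = 0.10
    freeze_shared: bool = False
    unlabeled_same_view: bool = False
    seed: int = 0

    def validate(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.rampup_epochs > self.epochs:
            raise ValueError("rampup_epochs must be <= epochs")
        return self


def consistency_weight(epoch: int, cfg: SemiTrainConfig) -> float:
    """Sigmoid-shaped ramp: 0 -> consistency_weight_max over rampup_epochs."""
    if cfg.consistency_weight_max == 0:
        return 0.0
    if cfg.rampup_epochs <= 0:
        return cfg.consistency_weight_max
    t = min(epoch / cfg.rampup_epochs, 1.0)
    return float(cfg.consistency_weight_max * np.exp(-5.0 * (1.0 - t) ** 2))


class DataError(ValueError):
    pass


def train_semisupervised(pair: TeacherStudentPair, cohort: PhantomCohort,
                         screen: GeneScreen, cfg: SemiTrainConfig | None = None):
    """Mean-Teacher training on the cohort's labeled + unlabeled train split.

    Returns (student, history); history logs per-epoch supervised loss,
    consistency loss, ramp weight and validation AUC.
    """
    cfg = (cfg or SemiTrainConfig()).validate()
    pair.alpha = cfg.alpha
    student, teacher = pair.student, pair.teacher
    labeled = np.asarray(cohort.split["train_labeled"])
    unlabeled = np.asarray(cohort.split["train_unlabeled"])
    if len(labeled) == 0:
        raise DataError("no labeled training samples")
    if len(unlabeled) == 0 and cfg.consistency_weight_max > 0:
        warnings.warn("no unlabeled data: consistency term disabled, "
                      "training degrades to supervised")
    expr = screen.transform(cohort.expression_matrix())
    rng_split = np.random.default_rng([cfg.seed, 1])
    rng_batch = np.random.default_rng([cfg.seed, 2])
    rng_unl = np.random.default_rng([cfg.seed, 3])
    rng_noise = np.random.default_rng([cfg.seed, 4])
    n_val = max(int(round(cfg.val_fraction * len(labeled))), 1) if len(labeled) > 4 else 0
    perm = rng_split.permutation(labeled)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if cfg.freeze_shared:
        student.body.set_requires_grad(False)
        params = [p for p in student.parameters() if p.requires_grad]
    else:
        params = student.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate)
    history = {"sup_loss": [], "cons_loss": [], "weight": [], "val_auc": []}
    for epoch in range(cfg.epochs):
        w = consistency_weight(epoch, cfg)
        if len(unlabeled) == 0:
            w = 0.0
        order = rng_batch.permutation(train_idx)
        sup_losses, cons_losses = [], []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            student.train()
            x = Tensor(cohort.images(batch))
            g = Tensor(expr[batch])
            logits = student.forward_logits(x, g)
            sup = bce_with_logits(logits, cohort.labels(batch))
            loss = sup
            cons_val = 0.0
            if w > 0:
                u = rng_unl.choice(unlabeled, size=min(cfg.batch_size, len(unlabeled)),
                                   replace=False)
                xu = cohort.images(u)
                gu = Tensor(expr[u])
                n1 = rng_noise.normal(0, cfg.noise_sd, xu.shape).astype(np.float32)
                n2 = n1 if cfg.unlabeled_same_view else \
                    rng_noise.normal(0, cfg.noise_sd, xu.shape).astype(np.float32)
                p_student = student.forward_logits(Tensor(xu + n1), gu).sigmoid()
                teacher.eval()
                with no_grad():
                    p_teacher = teacher.forward_logits(Tensor(xu + n2), gu).sigmoid()
                diff = p_student - Tensor(p_teacher.data)
                cons = (diff * diff).mean()
                loss = sup + w * cons
                cons_val = float(cons.data)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ema_update(pair)
            sup_losses.append(float(sup.data))
            cons_losses.append(cons_val)
        history["sup_loss"].append(float(np.mean(sup_losses)))
        history["cons_loss"].append(float(np.mean(cons_losses)))
        history["weight"].append(w)
        if len(val_idx):
            p = predict(student, cohort.images(val_idx), expr[val_idx])
            auc, _ = auc_trapezoid(p, cohort.labels(val_idx))
            history["val_auc"].append(auc)
        else:
            history["val_auc"].append(None)
    return student, history


def predict(model: StudentModel, images: np.ndarray, genes_screened: np.ndarray,
            batch_size: int = 32) -> np.ndarray:
    """Mutation probabilities for (B,1,H,W) images + screened gene vectors."""
    images = np.asarray(images, dtype=np.float32)
    genes_screened = np.asarray(genes_screened, dtype=np.float32)
    if genes_screened.shape[-1] != model.gene_k:
        raise ValueError(f"gene vector length {genes_screened.shape[-1]} does not "
                         f"match the training screen (k={model.gene_k})")
    model.eval()
    out = []
    with no_grad():
        for start in range(0, len(images), batch_size):
            sl = slice(start, start + batch_size)
            p = model(Tensor(images[sl]), Tensor(genes_screened[sl]))
            out.append(p.data)
    return np.concatenate(out)
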
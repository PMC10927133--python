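"""Gene screening and embedding.

The expression matrix (samples x genes) is screened down to the K genes most
associated with the binary mutation label, scored on *labeled training
samples only* — the screen must never see test rows or unlabeled labels.
Screened vectors are z-scored with a scaler fitted on the same samples and
mapped to a low-dimensional embedding by a two-layer MLP that trains jointly
with the classifier.

Default scorer is the absolute point-biserial correlation (equivalent to a
Pearson correlation against the 0/1 label); a mutual-information scorer is
available behind the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor


class DataError(ValueError):
    pass


def point_biserial_scores(expr: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """|corr(gene, label)| per gene; constant genes score exactly 0."""
    y = labels.astype(np.float64)
    x = expr.astype(np.float64)
    xm = x - x.mean(axis=0)
    ym = y - y.mean()
    sx = np.sqrt((xm ** 2).sum(axis=0))
    sy = np.sqrt((ym ** 2).sum())
    num = xm.T @ ym
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sx > 0) & (sy > 0), num / (sx * sy + (sx == 0)), 0.0)
    return np.abs(r)


def mutual_information_scores(expr: np.ndarray, labels: np.ndarray,
                              seed: int = 0) -> np.ndarray:
    from sklearn.feature_selection import mutual_info_classif
    return mutual_info_classif(expr, labels, random_state=seed)


_SCORERS = {
    "point_biserial": point_biserial_scores,
    "mutual_information": mutual_information_scores,
}


@dataclass
class GeneScreen:
    """Fitted gene screen: scores, selected columns and the z-score scaler."""

    scores: np.ndarray          # (n_genes,)
    selected: np.ndarray        # (k,) ordered by decreasing score, ties by index
    mean: np.ndarray            # (k,) fitted on labeled training samples
    sd: np.ndarray              # (k,) zeros replaced by 1
    scorer: str = "point_biserial"

    @property
    def k(self) -> int:
        return len(self.selected)

    def transform(self, expr: np.ndarray) -> np.ndarray:
        """Select + z-score rows of a (n, n_genes) matrix."""
        expr = np.asarray(expr)
        sub = expr[..., self.selected]
        return ((sub - self.mean) / self.sd).astype(np.float32)

    def to_json(self) -> str:
        return json.dumps({
            "scorer": self.scorer,
            "scores": self.scores.tolist(),
            "selected": self.selected.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "GeneScreen":
        d = json.loads(text)
        return cls(scores=np.array(d["scores"]), selected=np.array(d["selected"], dtype=int),
                   mean=np.array(d["mean"]), sd=np.array(d["sd"]), scorer=d["scorer"])


def select_genes(expr: np.ndarray, labels: np.ndarray, k: int = 115,
                 scorer: str = "point_biserial") -> GeneScreen:
    """Screen to the top-k label-associated genes and fit the scaler.

    ``expr``/``labels`` must already be restricted to labeled training
    samples; both classes must be present with >= 2 samples each.
    """
    expr = np.asarray(expr)
    labels = np.asarray(labels).astype(int)
    if expr.ndim != 2 or len(expr) != len(labels):
        raise DataError("expr must be (n_samples, n_genes) aligned with labels")
    if not np.isfinite(expr).all():
        raise DataError("expression matrix contains non-finite values")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise DataError(f"need >= 2 samples per class, got counts {counts.tolist()}")
    if scorer not in _SCORERS:
        raise DataError(f"unknown scorer '{scorer}'; options: {sorted(_SCORERS)}")
    scores = np.asarray(_SCORERS[scorer](expr, labels), dtype=float)
    k_eff = min(k, expr.shape[1])
    # descending score, ties broken by ascending column index (stable sort)
    order = np.argsort(-scores, kind="stable")
    selected = order[:k_eff]
    sub = expr[:, selected]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return GeneScreen(scores=scores, selected=selected, mean=mean, sd=sd, scorer=scorer)


class GeneMLP(nn.Module):
    """K -> hidden -> embed_dim MLP producing the gene embedding G."""

    def __init__(self, k: int, hidden: int = 64, embed_dim: int = 32):
        super().__init__()
        self.k, self.embed_dim = k, embed_dim
        self.fc1 = nn.Linear(k, hidden)
        self.fc2 = nn.Linear(hidden, embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.k:
            raise ValueError(f"expected {self.k} screened genes, got {x.shape[-1]}")
        return self.fc2(self.fc1(x).relu())


def embed_genes(x: np.ndarray, mlp: GeneMLP) -> np.ndarray:
    """Embed screened+scaled vectors (n, k) -> (n, embed_dim)."""
    out = mlp(Tensor(np.asarray(x, dtype=np.float32)))
    return out.data
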
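"""Classification metrics: confusion counts, the six-metric report and a
light stratified k-fold harness.

AUC is computed two ways on purpose — trapezoid integration of the ROC curve
and the pairwise probability P(score_pos > score_neg) + 0.5 * P(tie) — and
the two must coincide; the equivalence is asserted in the test suite rather
than collapsed into one code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Six classification metrics (fractions in [0,1]; ``None`` = undefined)."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    specificity: float | None
    auc: float | None
    f1: float | None
    roc: list[tuple[float, float]] = field(default_factory=list)

    def as_percent_dict(self) -> dict:
        out = {}
        for k in ("accuracy", "recall", "precision", "specificity", "auc", "f1"):
            v = getattr(self, k)
            out[k] = None if v is None else round(100.0 * v, 4)
        return out


def _check_binary(v: np.ndarray, name: str):
    if not np.isin(v, (0, 1)).all():
        raise DataError(f"{name} must contain only 0/1 values")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """2x2 counts with 1 = positive = mutation."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DataError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    _check_binary(y_true, "y_true")
    _check_binary(y_pred, "y_pred")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing")
        return None
    return num / den


def auc_pairwise(scores, y_true) -> float | None:
    """P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        warnings.warn("AUC undefined: only one class present")
        return None
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def auc_trapezoid(scores, y_true) -> tuple[float | None, list[tuple[float, float]]]:
    """Area under the ROC curve by trapezoid integration; returns (auc, roc)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        warnings.warn("AUC undefined: only one class present")
        return None, []
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores, dtype=float))
    return float(np.trapezoid(tpr, fpr)), list(zip(fpr.tolist(), tpr.tolist()))


def compute_metrics(counts: ConfusionCounts, scores=None, y_true=None) -> MetricsReport:
    """Assemble the six-metric report from hard counts and (optionally) scores."""
    ac = _safe_ratio(counts.tp + counts.tn, counts.n, "accuracy")
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn, "recall")
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp, "precision")
    specificity = _safe_ratio(counts.tn, counts.tn + counts.fp, "specificity")
    if recall is not None and precision is not None and (recall + precision) > 0:
        f1 = 2 * recall * precision / (recall + precision)
    else:
        f1 = None
    auc, roc = (None, [])
    if scores is not None and y_true is not None:
        if counts.n != len(np.asarray(y_true)):
            raise DataError("counts inconsistent with y_true length")
        auc, roc = auc_trapezoid(scores, y_true)
    return MetricsReport(accuracy=ac, recall=recall, precision=precision,
                         specificity=specificity, auc=auc, f1=f1, roc=roc)


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold scores at 0.5 and produce the full report."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return compute_metrics(confusion_counts(y_true, y_pred), scores, y_true)


def kfold_evaluate(model_factory, X, y, k: int = 5, seed: int = 0):
    """Stratified k-fold evaluation.

    ``model_factory()`` must return an object with ``fit(X, y)`` and
    ``predict_proba_1(X) -> scores``.  Returns (per-fold reports, summary)
    where summary maps metric -> (mean, sd) over folds, as percentages.
    """
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if k < 2:
        raise DataError("k must be >= 2")
    if counts.min() < k:
        raise DataError(f"stratification error: a class has {counts.min()} < k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(X, y):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_proba_1(X[test_idx])
        reports.append(evaluate_predictions(y[test_idx], scores))
    summary = {}
    for key in ("accuracy", "recall", "precision", "specificity", "auc", "f1"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if vals:
            summary[key] = (float(np.mean(vals) * 100), float(np.std(vals) * 100))
        else:
            summary[key] = (None, None)
    return reports, summary


def dice_coefficient(pred_mask, true_mask, eps: float = 0.0) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(true_mask).astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float((2.0 * np.logical_and(p, t).sum() + eps) / (denom + eps))
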
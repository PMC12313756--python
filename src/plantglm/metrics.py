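"""Evaluation metrics: MCC, macro-averaged PR/ROC summaries, and R².

Thin, convention-pinning wrappers over scikit-learn: MCC uses the
degenerate-denominator = 0 convention; macro averaging covers the donor
and acceptor classes by default (one-vs-rest), with an option to include
all classes; average precision is the step-interpolated area under the
precision-recall curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    r2_score,
    roc_auc_score,
    roc_curve,
)

__all__ = ["EvaluationReport", "mcc", "macro_pr_roc", "r_squared"]

logger = logging.getLogger(__name__)

SPLICE_CLASSES = ("donor", "acceptor", "negative")
MACRO_CLASSES = ("donor", "acceptor")


@dataclass
class EvaluationReport:
    """Named metric values for one evaluated task."""

    task_id: str
    metrics: dict[str, float]
    n_samples: int
    class_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, object]:
        return {
            "task_id": self.task_id,
            "metrics": self.metrics,
            "n_samples": self.n_samples,
            "class_counts": self.class_counts,
        }


def mcc(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Matthews correlation coefficient for binary labels in {0, 1}.

    Computed from the 2x2 confusion counts; returns 0.0 when any marginal
    is zero (all-one-class truth or prediction).
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def macro_pr_roc(
    y_true: Sequence[str],
    scores: np.ndarray,
    classes: Sequence[str] = SPLICE_CLASSES,
    macro_over: Sequence[str] | None = None,
    include_all_classes: bool = False,
    return_curves: bool = False,
):
    """One-vs-rest average precision and ROC AUC, macro-averaged.

    ``scores`` is (n_samples, n_classes) aligned with ``classes``.  The
    macro average covers the donor and acceptor classes by default;
    ``include_all_classes`` extends it to every class.  Classes with a
    single-class ground truth are skipped with a warning.

    Returns ``(macro_ap, macro_auroc)`` or, with ``return_curves``, a
    third dict of per-class PR/ROC curves and values.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] != len(classes):
        raise ValueError("scores must be (n_samples, n_classes)")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if macro_over is None:
        macro_over = tuple(classes) if include_all_classes else MACRO_CLASSES

    per_class: dict[str, dict[str, object]] = {}
    aps, rocs = [], []
    for ci, cls in enumerate(classes):
        truth = (y == cls).astype(int)
        if truth.min() == truth.max():
            logger.warning("class %r has single-class ground truth; skipped", cls)
            continue
        ap = float(average_precision_score(truth, s[:, ci]))
        auroc = float(roc_auc_score(truth, s[:, ci]))
        entry: dict[str, object] = {"ap": ap, "auroc": auroc}
        if return_curves:
            prec, rec, _ = precision_recall_curve(truth, s[:, ci])
            fpr, tpr, _ = roc_curve(truth, s[:, ci])
            entry.update(precision=prec, recall=rec, fpr=fpr, tpr=tpr)
        per_class[cls] = entry
        if cls in macro_over:
            aps.append(ap)
            rocs.append(auroc)
    if not aps:
        raise ValueError("no usable class in the macro-average set")
    macro_ap = float(np.mean(aps))
    macro_auroc = float(np.mean(rocs))
    if return_curves:
        return macro_ap, macro_auroc, per_class
    return macro_ap, macro_auroc


def r_squared(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (can be negative)."""
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape or t.size < 2:
        raise ValueError("need equal-length inputs with at least 2 values")
    if np.var(t) == 0:
        raise ValueError("y_true has zero variance; R^2 undefined")
    return float(r2_score(t, p))
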
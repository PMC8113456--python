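"""Classification validation: confusion metrics, ROC curves and AUC.

Rates are stored as raw fractions; percentage formatting (1 decimal by
convention) is cosmetic and applied only at serialization time. Undefined
ratios (empty denominators) are reported as ``None``, never coerced to 0.

Sensitivity/specificity depend on which class is declared positive; study
reports sometimes quote them with the remission class as reference, so
:meth:`ClassificationReport.swapped` exposes the opposite orientation of
the same confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

__all__ = ["ClassificationReport", "confusion_metrics", "roc_auc", "build_report"]


def _pct(x):
    return None if x is None else round(100.0 * x, 1)


@dataclass
class ClassificationReport:
    """Confusion counts and derived rates for one evaluated partition."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_label: str
    negative_label: str
    partition: str | None = None
    roc_points: np.ndarray | None = None   # (k, 2) columns (FPR, TPR)
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self):
        return (self.tp + self.tn) / self.n if self.n else None

    @property
    def sensitivity(self):
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self):
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def precision(self):
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f_score(self):
        p, s = self.precision, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2 * p * s / (p + s)

    def swapped(self) -> "ClassificationReport":
        """The same confusion matrix referenced to the other class."""
        return replace(
            self, tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp,
            positive_label=self.negative_label, negative_label=self.positive_label,
            roc_points=None, auc=None,
        )

    def to_dict(self, percent: bool = True) -> dict:
        conv = _pct if percent else (lambda x: x)
        d = {
            "partition": self.partition,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": conv(self.accuracy),
            "sensitivity": conv(self.sensitivity),
            "specificity": conv(self.specificity),
            "precision": conv(self.precision),
            "f_score": conv(self.f_score),
        }
        if self.auc is not None:
            d["auc"] = round(self.auc, 4)
        return d


def confusion_metrics(y_true, y_pred, positive_label,
                      negative_label=None, partition=None) -> ClassificationReport:
    """Confusion counts and rates for binary labels."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise DataError("empty input")
    if len(y_true) != len(y_pred):
        raise DataError("y_true and y_pred lengths differ")
    labels = set(y_true) | set(y_pred)
    others = labels - {positive_label}
    if negative_label is None:
        if len(others) > 1:
            raise DataError(f"ambiguous reference class among {sorted(map(str, others))}")
        negative_label = others.pop() if others else "rest"
    unknown = labels - {positive_label, negative_label}
    if unknown:
        raise DataError(f"labels outside the declared pair: {sorted(map(str, unknown))}")
    tp = sum(t == positive_label and p == positive_label for t, p in zip(y_true, y_pred))
    fn = sum(t == positive_label and p != positive_label for t, p in zip(y_true, y_pred))
    fp = sum(t != positive_label and p == positive_label for t, p in zip(y_true, y_pred))
    tn = sum(t != positive_label and p != positive_label for t, p in zip(y_true, y_pred))
    return ClassificationReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        positive_label=positive_label, negative_label=negative_label,
        partition=partition,
    )


def roc_auc(y_true, scores, positive_label):
    """ROC points by descending-threshold sweep and trapezoidal AUC.

    Tied scores advance TP and FP jointly (diagonal segments), which makes
    the trapezoidal AUC equal the Mann-Whitney concordant-pair statistic
    (ties counted 1/2) exactly.

    Returns ``(points, auc)`` with ``points`` an ``(k, 2)`` array of
    (FPR, TPR) from (0, 0) to (1, 1).
    """
    y_true = np.asarray(list(y_true))
    scores = np.asarray(scores, dtype=float)
    if scores.size != y_true.size:
        raise DataError("scores and labels lengths differ")
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present to build a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = pos[order].astype(float)
    # group tied scores
    boundaries = np.where(np.diff(s_sorted) != 0)[0]
    ends = np.append(boundaries, s_sorted.size - 1)
    tps = np.cumsum(pos_sorted)[ends]
    fps = (ends + 1) - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def build_report(partitions: dict, positive_label: str,
                 negative_label: str | None = None) -> dict:
    """Assemble per-partition reports.

    ``partitions`` maps a tag (``"training"``, ``"cross-validation"``,
    ``"test"``) to ``(y_true, y_pred)`` or ``(y_true, y_pred, scores)``.
    A partition supplied as ``None`` is reported as an explicit gap
    (``None`` value) rather than dropped silently.
    """
    out: dict[str, ClassificationReport | None] = {}
    for tag, payload in partitions.items():
        if payload is None:
            out[tag] = None
            continue
        y_true, y_pred, *rest = payload
        rep = confusion_metrics(y_true, y_pred, positive_label,
                                negative_label, partition=tag)
        if rest and rest[0] is not None:
            rep.roc_points, rep.auc = roc_auc(y_true, rest[0], positive_label)
        out[tag] = rep
    return out
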
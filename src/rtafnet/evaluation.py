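"""Evaluation metrics and error analysis for binary AF detection.

Accuracy, per-class and support-weighted precision/recall/F1 from the
confusion matrix (AF is the positive class), trapezoidal ROC/AUC, the
per-rhythm error-analysis table that separates atrial flutter from the
binary labels, and the zero-shot cross-dataset evaluation protocol.

The support-weighted averaging convention makes weighted recall equal to
accuracy identically (each class's recall is weighted by its share of true
samples), which is the reporting convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AF, NONAF, Window

__all__ = [
    "ConfusionCounts", "MetricsReport", "RhythmErrorRow",
    "confusion", "metrics_from_confusion", "roc_auc",
    "rhythm_error_analysis", "evaluate_model", "cross_db_evaluate",
]

# fine rhythms whose clinically correct binary call is AF
_AF_TYPE = {"AF", "AFL"}


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with AF as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Percentages in [0, 100]; ``per_class`` maps label -> dict of
    precision/recall/f1/support, ``weighted`` holds the support-weighted
    averages.  ``zero_division`` flags any 0/0 metric cell defined as 0."""

    accuracy: float
    per_class: dict
    weighted: dict
    counts: ConfusionCounts
    auc: float | None = None
    zero_division: bool = False
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Binary AF-detection metrics (%, AF positive)",
            f"  n = {self.counts.total}  "
            f"(TP={self.counts.tp} TN={self.counts.tn} "
            f"FP={self.counts.fp} FN={self.counts.fn})",
            f"  accuracy           {self.accuracy:6.2f}",
        ]
        for cls, m in self.per_class.items():
            lines.append(
                f"  {cls:<6} precision {m['precision']:6.2f}  "
                f"recall {m['recall']:6.2f}  F1 {m['f1']:6.2f}  "
                f"support {m['support']}"
            )
        w = self.weighted
        lines.append(
            f"  weighted precision {w['precision']:6.2f}  "
            f"recall {w['recall']:6.2f}  F1 {w['f1']:6.2f}"
        )
        if self.auc is not None:
            lines.append(f"  AUC                {self.auc:6.2f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RhythmErrorRow:
    """One row of the fine-grained error table."""

    rhythm: str
    total: int
    predicted_af: int
    predicted_nonaf: int
    error_rate: float  # percent in the clinically wrong column

    def __post_init__(self) -> None:
        if self.predicted_af + self.predicted_nonaf != self.total:
            raise ValueError("predicted columns must sum to the total")


def confusion(labels: list[str], predictions: list[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN over paired label/prediction sequences."""
    if len(labels) != len(predictions) or not labels:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    tp = sum(l == AF and p == AF for l, p in zip(labels, predictions))
    tn = sum(l == NONAF and p == NONAF for l, p in zip(labels, predictions))
    fp = sum(l == NONAF and p == AF for l, p in zip(labels, predictions))
    fn = sum(l == AF and p == NONAF for l, p in zip(labels, predictions))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def metrics_from_confusion(counts: ConfusionCounts) -> MetricsReport:
    """Per-class and support-weighted precision/recall/F1 plus accuracy.

    Each class is treated in turn as the positive class; weighted averages
    use the true-sample counts (supports) as weights.  0/0 cells are
    defined as 0 and flagged.
    """
    c = counts
    flag = False
    accuracy = (c.tp + c.tn) / c.total

    per_class = {}
    for cls, tp, fp, fn, support in (
        (AF, c.tp, c.fp, c.fn, c.tp + c.fn),
        (NONAF, c.tn, c.fn, c.fp, c.tn + c.fp),
    ):
        prec, f1_ = _safe_div(tp, tp + fp)
        flag |= f1_
        rec, f2_ = _safe_div(tp, tp + fn)
        flag |= f2_
        f1, f3_ = _safe_div(2 * prec * rec, prec + rec)
        flag |= f3_
        per_class[cls] = {
            "precision": 100 * prec, "recall": 100 * rec,
            "f1": 100 * f1, "support": support,
        }

    weighted = {}
    for key in ("precision", "recall", "f1"):
        weighted[key] = sum(
            m[key] * m["support"] for m in per_class.values()
        ) / c.total
    return MetricsReport(
        accuracy=100 * accuracy, per_class=per_class, weighted=weighted,
        counts=c, zero_division=flag,
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal AUC over all score thresholds.

    ``scores`` are AF probabilities (higher = more AF-like).  Returns
    ``(auc, fpr, tpr)``; the trapezoidal area equals the rank statistic
    (fraction of (AF, NonAF) pairs correctly ordered, ties counted 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == AF else 0 for l in labels])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # keep only the last point of each tied-score run
    keep = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def rhythm_error_analysis(
    windows: list[Window], predictions: list[str]
) -> list[RhythmErrorRow]:
    """Per-fine-rhythm counts of predicted AF / NonAF.

    The error rate of a rhythm is the fraction of its windows in the
    *clinically* wrong column: predicted NonAF for true AF, predicted AF
    for everything else — including atrial flutter, which the binary
    training labels fold into AF but which is a distinct arrhythmia, so an
    AF call on an AFL window counts as a (clinically relevant) confusion.
    """
    if len(windows) != len(predictions):
        raise ValueError("windows and predictions must be equal length")
    tab: dict[str, list[int]] = {}
    for w, p in zip(windows, predictions):
        row = tab.setdefault(w.fine_rhythm, [0, 0])
        row[0 if p == AF else 1] += 1
    rows = []
    for rhythm in sorted(tab, key=lambda r: (r not in _AF_TYPE, r)):
        paf, pnon = tab[rhythm]
        total = paf + pnon
        wrong = pnon if rhythm == "AF" else paf
        rows.append(RhythmErrorRow(
            rhythm=rhythm, total=total, predicted_af=paf,
            predicted_nonaf=pnon, error_rate=100.0 * wrong / total,
        ))
    return rows


def _predict(model, windows: list[Window], batch_size: int = 256):
    X = np.stack([w.samples for w in windows])
    probs = []
    for i in range(0, len(X), batch_size):
        probs.append(model.predict_proba(X[i : i + batch_size]))
    p = np.vstack(probs)
    preds = [AF if p[i, 1] >= p[i, 0] else NONAF for i in range(len(p))]
    return p[:, 1], preds


def evaluate_model(
    model, test_windows: list[Window], fine_rhythm: bool = True
) -> tuple[MetricsReport, list[RhythmErrorRow], tuple[np.ndarray, np.ndarray]]:
    """Full deterministic evaluation of a trained model on a test split.

    Dropout is disabled (eval mode); predictions are argmax at threshold
    0.5.  Returns the metrics report (including AUC), the per-rhythm error
    table, and the ROC curve points.
    """
    if not test_windows:
        raise ValueError("empty test split")
    model.eval()
    scores, preds = _predict(model, test_windows)
    labels = [w.label for w in test_windows]
    report = metrics_from_confusion(confusion(labels, preds))
    try:
        auc, fpr, tpr = roc_auc(scores, labels)
        report.auc = 100.0 * auc
    except ValueError:
        fpr = tpr = np.array([])
    rows = rhythm_error_analysis(test_windows, preds) if fine_rhythm else []
    return report, rows, (fpr, tpr)


def cross_db_evaluate(
    model, target_windows: list[Window],
    source_tag: str = "source", target_tag: str = "target",
) -> MetricsReport:
    """Zero-shot transfer: evaluate a model trained on one dataset directly
    on another dataset's test windows, with provenance tags attached."""
    report, _, _ = evaluate_model(model, target_windows, fine_rhythm=False)
    report.provenance = {"source": source_tag, "target": target_tag}
    return report
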
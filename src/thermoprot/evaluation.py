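"""Binary-classification metrics: the eight-metric report.

Recall, Precision, Accuracy, F1, MCC and Specificity are computed from
exact confusion counts at a fixed threshold; AUROC is the rank
(Mann-Whitney) statistic with ties counted half, and AUPRC is the
step-interpolated average precision.  Positive class is label 1
(thermophilic) throughout.

Degenerate denominators never raise: ratio metrics fall back to 0 and
the report carries a ``degenerate`` flag listing which ones did.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

#: column order used for one-row TSV reports
METRIC_ORDER = (
    "Recall", "Precision", "Accuracy", "F1", "MCC", "Specificity", "AUROC", "AUPRC",
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvaluationReport:
    Recall: float
    Precision: float
    Accuracy: float
    F1: float
    MCC: float
    Specificity: float
    AUROC: float
    AUPRC: float
    counts: ConfusionCounts
    threshold: float = 0.5
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_ORDER}

    def to_json(self) -> str:
        d = self.as_dict()
        d["counts"] = {k: getattr(self.counts, k) for k in ("TP", "TN", "FP", "FN")}
        d["threshold"] = self.threshold
        d["degenerate"] = self.degenerate
        return json.dumps(d, indent=2)

    def to_tsv_row(self, label: str = "") -> str:
        vals = "\t".join(f"{getattr(self, m):.6f}" for m in METRIC_ORDER)
        return f"{label}\t{vals}" if label else vals

    @staticmethod
    def tsv_header(label_col: str = "") -> str:
        cols = "\t".join(METRIC_ORDER)
        return f"{label_col}\t{cols}" if label_col else cols


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Exact confusion counts for binary labels/predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (set(np.unique(y)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels and predictions must be in {0, 1}")
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def threshold_metrics(c: ConfusionCounts) -> tuple[dict[str, float], list[str]]:
    """The six threshold metrics plus the list of degenerate ones.

    Recall = TP/(TP+FN); Precision = TP/(TP+FP);
    Accuracy = (TP+TN)/n; F1 = harmonic mean of Precision and Recall;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    Specificity = TN/(TN+FP).  A zero denominator yields 0 and is
    flagged.
    """
    degenerate: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    recall = ratio("Recall", c.TP, c.TP + c.FN)
    precision = ratio("Precision", c.TP, c.TP + c.FP)
    accuracy = ratio("Accuracy", c.TP + c.TN, c.n)
    f1 = ratio("F1", 2 * precision * recall, precision + recall)
    specificity = ratio("Specificity", c.TN, c.TN + c.FP)
    denom2 = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom2 == 0:
        degenerate.append("MCC")
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom2)
    metrics = {
        "Recall": recall,
        "Precision": precision,
        "Accuracy": accuracy,
        "F1": f1,
        "MCC": mcc,
        "Specificity": specificity,
    }
    return metrics, degenerate


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outranks a random negative (ties half)."""
    y = np.asarray(labels, dtype=int)
    if len(set(np.unique(y))) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Step-interpolated average precision (no trapezoid optimism)."""
    y = np.asarray(labels, dtype=int)
    if len(set(np.unique(y))) < 2:
        raise ValueError("AUPRC needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def evaluate(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> EvaluationReport:
    """Full eight-metric report from scores at a decision threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {s.shape}")
    preds = (s >= threshold).astype(int)
    c = confusion(y, preds)
    m, degenerate = threshold_metrics(c)
    return EvaluationReport(
        **m,
        AUROC=auroc(y, s),
        AUPRC=auprc(y, s),
        counts=c,
        threshold=threshold,
        degenerate=degenerate,
    )
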
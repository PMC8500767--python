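"""Segmentation and slide-level evaluation metrics.

Pixelwise confusion counts, precision/recall/F1, the Jaccard index in both
its set form |S ∩ M| / |S ∪ M| and its confusion-count form
TP / (TP + FP + FN) (the IoU identity), and per-class slide-accuracy tables
with the tumor average taken as the mean of the macro/micro/ITC class
accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SLIDE_CLASSES = ("negative", "macro", "micro", "itc")
TUMOR_CLASSES = ("macro", "micro", "itc")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def confusion(pred_mask, gt_mask):
    """Pixelwise confusion counts of two binary masks of equal shape."""
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(gt_mask, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def precision_recall_f1(c):
    """(precision, recall, F1) from confusion counts.

    Undefined ratios (empty prediction or empty truth) are reported as 0
    with a warning rather than raising.
    """
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        warnings.warn("precision/recall undefined for empty prediction or truth; returning 0")
        precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
        recall = c.tp / (c.tp + c.fn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def jaccard(pred_mask, gt_mask):
    """Jaccard index |S ∩ M| / |S ∪ M| of two binary masks.

    Equals TP / (TP + FP + FN); two empty masks score 1 by convention (the
    prediction agrees there is nothing to find).
    """
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(gt_mask, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    union = np.sum(p | g)
    if union == 0:
        return 1.0
    return float(np.sum(p & g) / union)


def iou_from_counts(c):
    """Jaccard/IoU in confusion-count form TP / (TP + FP + FN)."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def tumor_average(class_accuracies):
    """Mean of the per-class tumor accuracies (macro, micro, ITC), in percent."""
    vals = [v for v in class_accuracies if v is not None and not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def evaluate_slide_set(pred_labels, true_labels):
    """Per-class slide accuracy table plus the tumor-average summary.

    Returns a DataFrame indexed by class with columns ``n``, ``correct`` and
    ``accuracy_pct`` (NaN for classes absent from the truth, which are also
    excluded from the average), with a final ``average_tumor`` row holding
    the mean of the macro/micro/ITC accuracies.
    """
    if len(pred_labels) != len(true_labels):
        raise ValueError("prediction and truth lists differ in length")
    for lab in list(pred_labels) + list(true_labels):
        if lab not in SLIDE_CLASSES:
            raise ValueError(f"unknown slide label {lab!r}; expected one of {SLIDE_CLASSES}")
    rows = {}
    for cls in SLIDE_CLASSES:
        idx = [i for i, t in enumerate(true_labels) if t == cls]
        n = len(idx)
        correct = sum(1 for i in idx if pred_labels[i] == cls)
        acc = 100.0 * correct / n if n else float("nan")
        rows[cls] = {"n": n, "correct": correct, "accuracy_pct": acc}
    avg = tumor_average([rows[c]["accuracy_pct"] for c in TUMOR_CLASSES
                         if rows[c]["n"] > 0])
    table = pd.DataFrame(rows).T
    table.loc["average_tumor"] = {"n": sum(rows[c]["n"] for c in TUMOR_CLASSES),
                                  "correct": np.nan, "accuracy_pct": avg}
    return table


def slide_table_markdown(table):
    """Render an evaluate_slide_set table as Markdown."""
    lines = ["| class | n | accuracy (%) |", "|---|---|---|"]
    for cls, row in table.iterrows():
        acc = row["accuracy_pct"]
        acc_s = "n/a" if isinstance(acc, float) and np.isnan(acc) else f"{acc:.2f}"
        n = "" if isinstance(row["n"], float) and np.isnan(row["n"]) else int(row["n"])
        lines.append(f"| {cls} | {n} | {acc_s} |")
    return "\n".join(lines)
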
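"""Pixel-level segmentation metrics: IoU, Dice, Precision, Recall, Specificity.

Foreground (1) is the positive class.  Degenerate ratios (empty
denominator, e.g. an empty mask matched by an empty prediction) resolve to
1.0, consistent with the smoothed-Dice convention used in training.

Two aggregation modes over an evaluation set:

* ``per_image`` (default) — mean of per-image scores;
* ``pooled`` — confusion counts summed over all images first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "segmentation_scores",
    "MetricsReport",
    "evaluate_masks",
]

SCORE_KEYS = ("iou", "dice", "precision", "recall", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _check_mask(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ContractViolation(f"{name}: mask values must be exactly 0 or 1")
    return a.astype(bool)


def confusion_counts(pred_mask, G) -> ConfusionCounts:
    """Pixel-wise TP/FP/FN/TN between a binary prediction and ground truth."""
    p = _check_mask(pred_mask, "pred_mask")
    g = _check_mask(G, "G")
    if p.shape != g.shape:
        raise ContractViolation(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()),
        tn=int((~p & ~g).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else 1.0


def segmentation_scores(counts: ConfusionCounts) -> dict:
    """The five standard scores from one confusion table."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    return {
        "iou": _ratio(tp, tp + fp + fn),
        "dice": _ratio(2 * tp, 2 * tp + fp + fn),
        "precision": _ratio(tp, tp + fp),
        "recall": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
    }


@dataclass
class MetricsReport:
    """Per-image score table plus the aggregate row."""

    per_image: pd.DataFrame
    summary: dict
    mode: str

    def to_csv(self, path):
        table = self.per_image.copy()
        summary_row = {"id": f"__{self.mode}_aggregate__", **self.summary}
        table = pd.concat([table, pd.DataFrame([summary_row])], ignore_index=True)
        table.to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {"mode": self.mode, **{k: float(v) for k, v in self.summary.items()}}


def evaluate_masks(pred_masks, true_masks, ids=None, mode: str = "per_image") -> MetricsReport:
    """Score a list of binary predictions against ground-truth masks."""
    if len(pred_masks) != len(true_masks):
        raise ContractViolation("prediction and ground-truth lists differ in length")
    if mode not in ("per_image", "pooled"):
        raise ContractViolation(f"unknown aggregation mode {mode!r}")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(pred_masks))]
    rows, counts_list = [], []
    for sid, p, g in zip(ids, pred_masks, true_masks):
        c = confusion_counts(p, g)
        counts_list.append(c)
        rows.append({"id": sid, **segmentation_scores(c)})
    table = pd.DataFrame(rows, columns=["id", *SCORE_KEYS])
    if mode == "per_image":
        summary = {k: float(table[k].mean()) for k in SCORE_KEYS}
    else:
        pooled = sum(counts_list[1:], counts_list[0])
        summary = segmentation_scores(pooled)
    return MetricsReport(per_image=table, summary=summary, mode=mode)
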
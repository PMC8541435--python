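"""Segmentation evaluation: confusion counts, precision/recall/F1, Dice
and Jaccard, with macro (per-image mean) and micro (pooled counts)
aggregation.

Degenerate conventions, applied uniformly: a 0/0 ratio is defined as 0;
comparing two empty masks gives Dice = Jaccard = 1 (nothing to miss).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "precision_recall_f1",
    "dice",
    "jaccard",
    "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    dice: float
    jaccard: float
    averaging: str
    per_image: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: str | Path) -> None:
        keys = ("precision", "recall", "f1", "dice", "jaccard")
        lines = ["image," + ",".join(keys)]
        for i, row in enumerate(self.per_image):
            lines.append(f"{i}," + ",".join(str(row[k]) for k in keys))
        lines.append(f"{self.averaging}," + ",".join(str(getattr(self, k)) for k in keys))
        Path(path).write_text("\n".join(lines) + "\n")


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts with foreground (1) as positive class."""
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise InputError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    p = _ratio(c.tp, c.tp + c.fp)
    r = _ratio(c.tp, c.tp + c.fn)
    f1 = _ratio(2.0 * p * r, p + r)
    return p, r, f1


def dice(c: ConfusionCounts) -> float:
    """2TP/(2TP+FP+FN); empty vs empty -> 1 by convention."""
    den = 2 * c.tp + c.fp + c.fn
    return 2.0 * c.tp / den if den else 1.0


def jaccard(c: ConfusionCounts) -> float:
    """TP/(TP+FP+FN); empty vs empty -> 1 by convention."""
    den = c.tp + c.fp + c.fn
    return c.tp / den if den else 1.0


def _metrics_dict(c: ConfusionCounts) -> dict:
    p, r, f1 = precision_recall_f1(c)
    return {"precision": p, "recall": r, "f1": f1, "dice": dice(c), "jaccard": jaccard(c)}


def evaluate_set(preds, gts, averaging: str = "macro") -> MetricReport:
    """Evaluate a list of predicted masks against ground truth.

    macro: mean of per-image metrics. micro: metrics of the counts pooled
    over all images (for which F1 and Dice coincide exactly).
    """
    if averaging not in ("macro", "micro"):
        raise InputError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    preds, gts = list(preds), list(gts)
    if len(preds) != len(gts):
        raise InputError(f"got {len(preds)} predictions vs {len(gts)} ground truths")
    if not preds:
        raise InputError("nothing to evaluate")
    counts = [confusion(p, g) for p, g in zip(preds, gts)]
    per_image = [dict(_metrics_dict(c), tp=c.tp, fp=c.fp, fn=c.fn, tn=c.tn)
                 for c in counts]
    if averaging == "macro":
        agg = {k: float(np.mean([m[k] for m in per_image]))
               for k in ("precision", "recall", "f1", "dice", "jaccard")}
    else:
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        agg = _metrics_dict(pooled)
    return MetricReport(precision=agg["precision"], recall=agg["recall"], f1=agg["f1"],
                        dice=agg["dice"], jaccard=agg["jaccard"], averaging=averaging,
                        per_image=per_image)
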
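"""Pixel-level segmentation evaluation.

Six standard metrics computed from the confusion counts of a binary mask
against ground truth: sensitivity (SE), specificity (SP), precision (PC),
Jaccard index (JA), Dice coefficient (DC) and accuracy (ACC).  A metric
whose denominator is zero is *undefined* (NaN) and excluded from set-level
averages rather than raised as an error.

Set-level evaluation reports the per-image mean (the ISIC-challenge
convention) as the headline number and the pooled-counts variant (counts
summed over all images first) alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import ShapeError

#: column order used in reports
METRIC_ORDER = ("ACC", "SE", "SP", "PC", "JA", "DC")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies: true/false positives and negatives."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass(frozen=True)
class MetricsReport:
    """The six metrics as fractions in [0,1]; NaN marks an undefined entry."""

    SE: float
    SP: float
    PC: float
    JA: float
    DC: float
    ACC: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_percent_row(self) -> dict[str, str]:
        return {k: (f"{100 * v:.2f}" if not math.isnan(v) else "--")
                for k, v in ((m, getattr(self, m)) for m in METRIC_ORDER)}


def confusion(pred_bin, gt) -> ConfusionCounts:
    """Confusion counts of two binary maps of identical shape."""
    pred_bin = np.asarray(pred_bin)
    gt = np.asarray(gt)
    if pred_bin.shape != gt.shape:
        raise ShapeError(f"shape mismatch: {pred_bin.shape} vs {gt.shape}")
    for name, arr in (("prediction", pred_bin), ("ground truth", gt)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    p = pred_bin.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        TP=int(np.count_nonzero(p & g)),
        FP=int(np.count_nonzero(p & ~g)),
        TN=int(np.count_nonzero(~p & ~g)),
        FN=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics(c: ConfusionCounts) -> MetricsReport:
    """SE, SP, PC, JA, DC, ACC from confusion counts; zero denominators give
    NaN entries."""
    return MetricsReport(
        SE=_ratio(c.TP, c.TP + c.FN),
        SP=_ratio(c.TN, c.TN + c.FP),
        PC=_ratio(c.TP, c.TP + c.FP),
        JA=_ratio(c.TP, c.TP + c.FN + c.FP),
        DC=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        ACC=_ratio(c.TN + c.TP, c.total),
    )


def evaluate_set(pred_probs, gts, threshold: float = 0.5
                 ) -> tuple[MetricsReport, MetricsReport, pd.DataFrame]:
    """Evaluate a set of probability maps against ground-truth masks.

    Each prediction is binarised at ``threshold``; returns the per-image
    mean report (NaN entries skipped), the pooled-counts report, and the
    per-image table.
    """
    if len(pred_probs) == 0:
        raise ValueError("evaluate_set needs at least one image")
    if len(pred_probs) != len(gts):
        raise ShapeError(f"{len(pred_probs)} predictions vs {len(gts)} ground truths")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for prob, gt in zip(pred_probs, gts):
        prob = np.asarray(prob)
        c = confusion((prob >= threshold).astype(np.uint8), gt)
        pooled = pooled + c
        rows.append(metrics(c).as_dict())
    table = pd.DataFrame(rows)
    mean = MetricsReport(**{k: float(table[k].mean(skipna=True)) for k in table})
    return mean, metrics(pooled), table


def report_table(named_reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Rows of percentage strings (2 decimals) in the standard column order."""
    return pd.DataFrame(
        {name: rep.as_percent_row() for name, rep in named_reports.items()}
    ).T[list(METRIC_ORDER)]
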
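"""Segmentation overlap metrics: DSC, Recall, VOE, RVD.

All four are defined from pixel counts of a predicted mask P against a
ground-truth mask G:

* ``DSC  = 2|P∩G| / (|P| + |G|)``
* ``Recall = TP / (TP + FN)``
* ``VOE  = |1 - |P∩G| / |P∪G||``  (Jaccard-based error)
* ``RVD  = ||P|/|G| - 1||``       (volume-only discrepancy)

Edge conventions (warned where applied): both masks empty gives DSC 1.0
and VOE 0.0; an empty ground truth makes Recall and RVD undefined (NaN).
Aggregation is the unweighted mean over samples, NaN-skipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "dsc", "recall",
           "voe", "rvd", "evaluate_pair", "report_from_pairs"]

METRIC_NAMES = ("dsc", "recall", "voe", "rvd")


@dataclass
class ConfusionCounts:
    """Pixelwise TP/FP/TN/FN tallies for one mask pair."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _validate(pred: np.ndarray, gt: np.ndarray):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if not np.all(np.isin(m, [0, 1])):
            raise ValueError(f"{name} mask is not binary")
    return pred.astype(bool), gt.astype(bool)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixelwise confusion counts."""
    p, g = _validate(pred, gt)
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient; both-empty convention: 1.0 (warned)."""
    p, g = _validate(pred, gt)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ + ng == 0:
        warnings.warn("both masks empty: DSC defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int(np.sum(p & g)) / (np_ + ng)


def recall(pred: np.ndarray, gt: np.ndarray) -> float:
    """Sensitivity TP/(TP+FN); NaN when the ground truth is empty."""
    p, g = _validate(pred, gt)
    if g.sum() == 0:
        warnings.warn("empty ground truth: recall undefined", stacklevel=2)
        return float("nan")
    return int(np.sum(p & g)) / int(g.sum())


def voe(pred: np.ndarray, gt: np.ndarray) -> float:
    """Volumetric overlap error |1 - |P∩G|/|P∪G||; both-empty: 0.0 (warned)."""
    p, g = _validate(pred, gt)
    union = int(np.sum(p | g))
    if union == 0:
        warnings.warn("both masks empty: VOE defined as 0.0", stacklevel=2)
        return 0.0
    return abs(1.0 - int(np.sum(p & g)) / union)


def rvd(pred: np.ndarray, gt: np.ndarray) -> float:
    """Relative volume difference ||P|/|G| - 1|; NaN for empty ground truth."""
    p, g = _validate(pred, gt)
    if g.sum() == 0:
        warnings.warn("empty ground truth: RVD undefined", stacklevel=2)
        return float("nan")
    return abs(int(p.sum()) / int(g.sum()) - 1.0)


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """All four metrics for one mask pair."""
    return {"dsc": dsc(pred, gt), "recall": recall(pred, gt),
            "voe": voe(pred, gt), "rvd": rvd(pred, gt)}


@dataclass
class MetricReport:
    """Per-sample metric rows plus their unweighted (NaN-skipping) means."""

    per_sample: pd.DataFrame
    aggregate: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        """CSV with one row per sample and a footer row of means."""
        footer = {"sample_id": "mean", **self.aggregate}
        table = pd.concat([self.per_sample, pd.DataFrame([footer])],
                          ignore_index=True)
        table.to_csv(path, index=False)


def report_from_pairs(pairs, sample_ids=None) -> MetricReport:
    """Build a report from an iterable of (pred, gt) mask pairs."""
    rows = []
    for i, (pred, gt) in enumerate(pairs):
        sid = sample_ids[i] if sample_ids is not None else f"sample_{i:04d}"
        rows.append({"sample_id": sid, **evaluate_pair(pred, gt)})
    per_sample = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aggregate = {m: float(np.nanmean(per_sample[m].to_numpy()))
                     for m in METRIC_NAMES}
    return MetricReport(per_sample=per_sample, aggregate=aggregate)
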
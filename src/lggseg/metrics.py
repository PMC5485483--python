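"""Overlap metrics for binary segmentations: DSC, PPV, sensitivity.

DSC = 2TP / (FP + 2TP + FN), PPV = TP / (TP + FP),
sensitivity = TP / (TP + FN), computed in 3D over the whole volume (one
value per case).  Degenerate denominators follow fixed conventions —
both masks empty: all three metrics are 1; an empty denominator
otherwise yields 1 for the ratio it degenerates (e.g. PPV of an empty
prediction) — and every such emission is flagged so cohort summaries can
exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_core import BinaryMask

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dsc",
    "ppv",
    "sensitivity",
    "evaluate_masks",
    "cohort_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise TP/FP/FN counts (TN implicit)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.labels > 0
    t = truth.labels > 0
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t))
    )


def dsc(c: ConfusionCounts) -> float:
    denom = c.fp + 2 * c.tp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def ppv(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return 1.0 if denom == 0 else c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def evaluate_masks(pred: BinaryMask, truth: BinaryMask, subject_id: str = "") -> dict:
    """All three metrics plus degenerate-denominator flags for one case."""
    c = confusion(pred, truth)
    flags = []
    if c.fp + 2 * c.tp + c.fn == 0:
        flags.append("both_empty")
    else:
        if c.tp + c.fp == 0:
            flags.append("empty_prediction")
        if c.tp + c.fn == 0:
            flags.append("empty_truth")
    return {
        "subject_id": subject_id,
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "dsc": dsc(c),
        "ppv": ppv(c),
        "sensitivity": sensitivity(c),
        "flags": ";".join(flags),
    }


def cohort_summary(per_subject: list[dict] | pd.DataFrame) -> pd.DataFrame:
    """Mean/median/quartiles of each metric over a cohort.

    Order-invariant; raises on an empty cohort.
    """
    df = pd.DataFrame(per_subject)
    if df.empty:
        raise ValueError("empty metric list")
    rows = {}
    for metric in ("dsc", "ppv", "sensitivity"):
        vals = df[metric].astype(float)
        rows[metric] = {
            "mean": vals.mean(),
            "median": vals.median(),
            "q1": vals.quantile(0.25),
            "q3": vals.quantile(0.75),
        }
    return pd.DataFrame(rows).T[["mean", "median", "q1", "q3"]]
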
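"""Intensity normalization with statistics fitted on training data.

Mean and standard deviation are pooled over brain voxels of the training
cohort and *preserved*: test volumes are normalized with the training
statistics, never their own.  Background (zero) voxels of skull-stripped
images are excluded from the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging_core import BinaryMask, Volume

__all__ = ["NormStats", "fit_normalizer", "apply_normalizer", "invert_normalizer"]


@dataclass
class NormStats:
    """Pooled intensity mean/std over training brain voxels."""

    mean: float
    std: float
    fitted_on: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError(f"std must be > 0, got {self.std}")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean, "std": self.std, "fitted_on": self.fitted_on})
        )

    @classmethod
    def from_json(cls, path) -> "NormStats":
        d = json.loads(Path(path).read_text())
        return cls(mean=d["mean"], std=d["std"], fitted_on=d.get("fitted_on", []))


def fit_normalizer(
    volumes: Sequence[Volume],
    brain_masks: Sequence[BinaryMask] | None = None,
) -> NormStats:
    """Fit pooled mean/std over the brain voxels of the training volumes.

    When no explicit brain masks are given, nonzero voxels are taken as
    brain (skull-stripped input is zero outside the head).

    Raises
    ------
    ValueError
        If no volumes are given or the pooled intensities are constant.
    """
    if len(volumes) == 0:
        raise ValueError("at least one volume is required")
    if brain_masks is not None and len(brain_masks) != len(volumes):
        raise ValueError("brain_masks must pair 1:1 with volumes")
    pools = []
    for i, vol in enumerate(volumes):
        if brain_masks is not None:
            brain_masks[i].check_aligned(vol)
            sel = brain_masks[i].labels > 0
        else:
            sel = vol.voxels != 0
        pools.append(vol.voxels[sel])
    pooled = np.concatenate(pools)
    if pooled.size == 0:
        raise ValueError("no brain voxels found in training volumes")
    mean = float(pooled.mean())
    std = float(pooled.std(ddof=0))
    if std == 0:
        raise ValueError("degenerate input: pooled intensities are constant (std = 0)")
    return NormStats(mean=mean, std=std, fitted_on=[v.subject_id for v in volumes])


def apply_normalizer(volume: Volume, stats: NormStats) -> Volume:
    """Return ``(volume - mean) / std`` with geometry unchanged."""
    return volume.with_voxels((volume.voxels - stats.mean) / stats.std)


def invert_normalizer(volume: Volume, stats: NormStats) -> Volume:
    """Undo :func:`apply_normalizer` (exact affine inverse)."""
    return volume.with_voxels(volume.voxels * stats.std + stats.mean)
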
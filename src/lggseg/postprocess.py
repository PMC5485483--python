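"""Morphological cleanup of CRF output masks.

Fixed three-stage order: keep the largest connected component of each
slice, drop slices whose retained region is not strictly larger than
300 pixels, then smooth in 3D with a 3x3x3 box (mean) filter rebinarized
at 0.5.  The first two stages only remove pixels; connectivity is
8-connected in-plane, and the box filter uses zero padding (outside the
head is background).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label

from .imaging_core import BinaryMask

__all__ = [
    "largest_component_per_slice",
    "area_filter",
    "smooth3d",
    "postprocess_mask",
    "DEFAULT_MIN_AREA",
]

DEFAULT_MIN_AREA = 300


def largest_component_per_slice(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 8-connected component of each slice.

    Equal-size ties go to the component whose first pixel comes earliest
    in row-major order; empty slices stay empty.
    """
    out = np.zeros_like(mask.labels)
    for z in range(mask.shape[0]):
        sl = mask.labels[z]
        if not sl.any():
            continue
        lab = cc_label(sl, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        best_size = sizes.max()
        winners = np.flatnonzero(sizes == best_size)
        if len(winners) == 1:
            keep = winners[0]
        else:
            flat = lab.ravel()
            keep = min(winners, key=lambda w: int(np.argmax(flat == w)))
        out[z] = (lab == keep).astype(np.uint8)
    return BinaryMask(out)


def area_filter(mask: BinaryMask, min_area: int = DEFAULT_MIN_AREA) -> BinaryMask:
    """Per slice, clear regions unless their area is strictly > min_area."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    out = mask.labels.copy()
    for z in range(mask.shape[0]):
        sl = out[z]
        if not sl.any():
            continue
        lab = cc_label(sl, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        drop = np.flatnonzero((sizes > 0) & (sizes <= min_area))
        if len(drop):
            sl[np.isin(lab, drop)] = 0
    return BinaryMask(out)


def smooth3d(mask: BinaryMask) -> BinaryMask:
    """3x3x3 box-filter smoothing, zero padded, rebinarized at 0.5.

    A voxel survives iff at least 14 of its 27 neighbours (itself
    included) are foreground — isolated voxels vanish, flat interiors
    are untouched.
    """
    if mask.shape[0] < 1:
        raise ValueError("mask must have at least one slice")
    means = uniform_filter(mask.labels.astype(np.float64), size=3, mode="constant", cval=0.0)
    return BinaryMask((means > 0.5).astype(np.uint8))


def postprocess_mask(mask: BinaryMask, min_area: int = DEFAULT_MIN_AREA) -> BinaryMask:
    """Full cleanup: largest component -> area filter -> 3D smoothing."""
    return smooth3d(area_filter(largest_component_per_slice(mask), min_area))
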
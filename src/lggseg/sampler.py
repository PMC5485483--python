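"""Unbalanced random sampling of labeled 33x33 training patches.

Tumor voxels are a tiny fraction of the brain, so patches are drawn with a
controlled tumor fraction (about 40% tumor-centred by default) rather than
uniformly.  Each patch is labeled by the class of its centre pixel.  For
the 3-slice fusion networks a patch carries the same 33x33 window cut from
slices z-1, z, z+1 (edge slices replicated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging_core import BinaryMask, Volume
from .preprocess import NormStats, apply_normalizer

__all__ = ["PATCH_SIZE", "PatchSet", "sample_patches", "build_training_set"]

PATCH_SIZE = 33
HALF = PATCH_SIZE // 2  # 16


@dataclass
class PatchSet:
    """A bag of labeled training patches.

    ``windows`` has shape ``(n, channels, 33, 33)``; ``centers`` holds the
    (slice, row, col) centre of each patch; ``labels`` the centre-pixel
    class.
    """

    windows: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    seed: int
    source: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.windows.shape[0] != n or self.centers.shape[0] != n:
            raise ValueError("windows, centers and labels must align")
        if self.windows.ndim != 4 or self.windows.shape[2:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"windows must be (n, c, 33, 33), got {self.windows.shape}")
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def channels(self) -> int:
        return self.windows.shape[1]

    @classmethod
    def concatenate(cls, parts: list["PatchSet"], seed: int) -> "PatchSet":
        return cls(
            windows=np.concatenate([p.windows for p in parts]),
            centers=np.concatenate([p.centers for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            seed=seed,
            source=sorted({s for p in parts for s in p.source}),
        )

    def shuffled(self, rng: np.random.Generator) -> "PatchSet":
        order = rng.permutation(len(self))
        return PatchSet(
            windows=self.windows[order],
            centers=self.centers[order],
            labels=self.labels[order],
            seed=self.seed,
            source=self.source,
        )


def _extract_window(vox: np.ndarray, z: int, r: int, c: int, channels: int) -> np.ndarray:
    """Cut a (channels, 33, 33) window centred at (z, r, c)."""
    n_slices = vox.shape[0]
    if channels == 1:
        zs = [z]
    else:
        zs = [min(max(z + dz, 0), n_slices - 1) for dz in (-1, 0, 1)]
    return np.stack([vox[zz, r - HALF : r + HALF + 1, c - HALF : c + HALF + 1] for zz in zs])


def _draw(rng: np.random.Generator, candidates: np.ndarray, k: int) -> np.ndarray:
    """Draw k rows, without replacement until exhausted, then with."""
    n = len(candidates)
    if k <= n:
        idx = rng.choice(n, size=k, replace=False)
    else:
        idx = np.concatenate([rng.permutation(n), rng.choice(n, size=k - n, replace=True)])
    return candidates[idx]


def sample_patches(
    volume: Volume,
    mask: BinaryMask,
    n_per_slice: int = 50,
    tumor_fraction: float = 0.4,
    channels: int = 1,
    seed: int = 0,
    brain_mask: BinaryMask | None = None,
) -> PatchSet:
    """Randomly extract labeled 33x33 patches with a fixed tumor fraction.

    Per slice, ``ceil(tumor_fraction * n_per_slice)`` centres are drawn
    from in-bounds tumor pixels (without replacement until exhausted) and
    the rest from in-bounds background brain pixels.  Background means
    brain tissue: nonzero voxels (or ``brain_mask``) with mask 0 — all-air
    patches carry no signal.  Slices with no background candidates are
    skipped; slices with no tumor candidates contribute background-only
    patches unless ``tumor_fraction == 1``.

    Reproducible: identical inputs and seed give an identical PatchSet.
    """
    mask.check_aligned(volume)
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError(f"tumor_fraction must be in [0,1], got {tumor_fraction}")
    ns, nr, nc = volume.shape
    if nr < PATCH_SIZE or nc < PATCH_SIZE:
        raise ValueError(
            f"slice size {(nr, nc)} smaller than the {PATCH_SIZE}x{PATCH_SIZE} patch"
        )
    if tumor_fraction > 0 and mask.labels.sum() == 0:
        raise ValueError("tumor_fraction > 0 but the mask contains no tumor voxels")

    brain = brain_mask.labels > 0 if brain_mask is not None else volume.voxels != 0
    interior = np.zeros((nr, nc), dtype=bool)
    interior[HALF : nr - HALF, HALF : nc - HALF] = True

    rng = np.random.default_rng(seed)
    n_tumor_req = math.ceil(tumor_fraction * n_per_slice)
    wins, cens, labs = [], [], []
    for z in range(ns):
        tum = np.argwhere((mask.labels[z] > 0) & interior)
        bg = np.argwhere((mask.labels[z] == 0) & brain[z] & interior)
        k_t = n_tumor_req if len(tum) else 0
        k_b = n_per_slice - k_t if len(bg) else 0
        picks = []
        if k_t:
            picks.append((_draw(rng, tum, k_t), 1))
        if k_b:
            picks.append((_draw(rng, bg, k_b), 0))
        for rows, lab in picks:
            for r, c in rows:
                wins.append(_extract_window(volume.voxels, z, int(r), int(c), channels))
                cens.append((z, int(r), int(c)))
                labs.append(lab)
    if not wins:
        raise ValueError("no valid patch centres found")
    return PatchSet(
        windows=np.stack(wins).astype(np.float64),
        centers=np.asarray(cens, dtype=np.int64),
        labels=np.asarray(labs, dtype=np.int64),
        seed=seed,
        source=[volume.subject_id],
    )


def build_training_set(
    cohort: list[tuple[Volume, BinaryMask]],
    stats: NormStats | None = None,
    n_per_slice: int = 50,
    tumor_fraction: float = 0.4,
    channels: int = 1,
    seed: int = 0,
) -> PatchSet:
    """Normalize each subject, sample patches, concatenate and shuffle.

    ``stats`` are the training-cohort normalization statistics; when None
    the volumes are assumed already normalized.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    parts = []
    for i, (vol, mask) in enumerate(cohort):
        if stats is not None:
            vol_n = apply_normalizer(vol, stats)
            brain = BinaryMask((vol.voxels != 0).astype(np.uint8))
        else:
            vol_n = vol
            brain = None
        sub_seed = int(rng.integers(0, 2**31 - 1))
        parts.append(
            sample_patches(
                vol_n,
                mask,
                n_per_slice=n_per_slice,
                tumor_fraction=tumor_fraction,
                channels=channels,
                seed=sub_seed,
                brain_mask=brain,
            )
        )
    combined = PatchSet.concatenate(parts, seed=seed)
    return combined.shuffled(rng)
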
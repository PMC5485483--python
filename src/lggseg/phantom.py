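"""Seeded synthetic lesion phantoms for end-to-end pipeline testing.

Each phantom emulates a skull-stripped T2-FLAIR acquisition of a
low-grade glioma: an ellipsoidal "brain" of roughly uniform tissue
intensity on a zero background, one or more hyperintense ellipsoidal
lesions of modest contrast spanning several slices, smooth low-frequency
background texture, additive Gaussian noise and an optional smooth
multiplicative bias field.  Ground truth is the exact rasterized lesion
support.  Everything derives from a single integer seed.

The lesion-to-background intensity gap is ``contrast`` times the noise
standard deviation; with ``noise_sd = 0`` the gap unit falls back to one
intensity unit (so noiseless phantoms stay separable by thresholding).
Background texture (smoothed Gaussian field) has SD 0.5 x noise_sd, so a
zero-noise phantom has a perfectly flat background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging_core import BinaryMask, Volume, write_mask, write_volume

__all__ = ["PhantomConfig", "generate_phantom", "generate_cohort", "ellipsoid_mask"]

BASE_INTENSITY = 100.0


@dataclass
class PhantomConfig:
    """Geometry, lesion statistics and noise of one synthetic subject.

    ``lesion_axes`` gives (min, max) ellipsoid semi-axes in voxels per
    axis order (slice, row, col); slice semi-axes of at least 1 make
    every lesion span >= 2 slices (2 mm slices vs 0.47 mm pixels, hence
    the much smaller through-plane extent).
    """

    shape: tuple[int, int, int] = (12, 96, 96)
    n_lesions: int = 1
    lesion_axes: tuple[tuple[float, float], ...] = ((1.5, 3.0), (8.0, 14.0), (8.0, 14.0))
    contrast: float = 3.0
    noise_sd: float = 10.0
    bias_field: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < m for s, m in zip(self.shape, (3, 33, 33))):
            raise ValueError(f"shape must be >= (3, 33, 33), got {self.shape}")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def ellipsoid_mask(shape: tuple[int, int, int], center: tuple[float, float, float],
                   axes: tuple[float, float, float]) -> np.ndarray:
    """Boolean rasterization of a solid axis-aligned ellipsoid."""
    zz, rr, cc = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / axes[0]) ** 2
        + ((rr - center[1]) / axes[1]) ** 2
        + ((cc - center[2]) / axes[2]) ** 2
    ) <= 1.0


def _brain_support(shape: tuple[int, int, int]) -> np.ndarray:
    ns, nr, nc = shape
    center = ((ns - 1) / 2, (nr - 1) / 2, (nc - 1) / 2)
    axes = (max(ns * 0.55, 1.5), nr * 0.45, nc * 0.45)
    return ellipsoid_mask(shape, center, axes)


def generate_phantom(config: PhantomConfig) -> tuple[Volume, BinaryMask]:
    """Generate one phantom volume and its ground-truth lesion mask.

    Raises a RuntimeError when a requested lesion cannot be placed fully
    inside the brain support after many attempts.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    brain = _brain_support(shape)
    gap_unit = config.noise_sd if config.noise_sd > 0 else 1.0

    vox = np.zeros(shape, dtype=np.float64)
    vox[brain] = BASE_INTENSITY
    if config.noise_sd > 0:
        texture = gaussian_filter(rng.standard_normal(shape), sigma=(1.0, 6.0, 6.0))
        texture *= 0.5 * config.noise_sd / max(texture[brain].std(), 1e-12)
        vox[brain] += texture[brain]

    mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(config.n_lesions):
        placed = False
        for _attempt in range(200):
            axes = tuple(
                rng.uniform(lo, hi) for lo, hi in config.lesion_axes
            )
            margin = [a + 1 for a in axes]
            center = tuple(
                rng.uniform(m, s - 1 - m) if s - 1 - m > m else (s - 1) / 2
                for s, m in zip(shape, margin)
            )
            les = ellipsoid_mask(shape, center, axes)
            if les.sum() == 0 or np.any(les & ~brain):
                continue
            if les.sum(axis=(1, 2)).astype(bool).sum() < 2:
                continue  # must span at least two slices
            mask |= les.astype(np.uint8)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a lesion with axes range {config.lesion_axes} "
                f"inside the brain support of shape {shape}"
            )
    vox[mask > 0] += config.contrast * gap_unit

    if config.bias_field:
        bias = gaussian_filter(rng.standard_normal(shape), sigma=(2.0, 20.0, 20.0))
        bias = 1.0 + 0.1 * bias / max(np.abs(bias[brain]).max(), 1e-12)
        vox[brain] *= bias[brain]
    if config.noise_sd > 0:
        vox[brain] += rng.normal(0.0, config.noise_sd, size=int(brain.sum()))

    volume = Volume(vox, subject_id=f"phantom-{config.seed}")
    return volume, BinaryMask(mask)


def generate_cohort(
    n_train: int,
    n_test: int,
    config: PhantomConfig,
    out_dir=None,
) -> tuple[list[tuple[Volume, BinaryMask]], list[tuple[Volume, BinaryMask]]]:
    """Generate independent train/test phantoms with derived per-subject seeds.

    Seeds derive deterministically from ``config.seed`` via a seed
    sequence.  With ``out_dir`` set, volumes, masks and a JSON manifest
    are written as NIfTI.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("cohort counts must be >= 1")
    child_seeds = [
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(n_train + n_test) % (2**31)
    ]
    subjects = []
    for i, s in enumerate(child_seeds):
        cfg = PhantomConfig(**{**asdict(config), "seed": s})
        vol, mask = generate_phantom(cfg)
        vol.subject_id = f"phantom-{i:03d}"
        subjects.append((vol, mask))
    train, test = subjects[:n_train], subjects[n_train:]
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest = {"master_seed": config.seed, "train": [], "test": []}
        for split, items in (("train", train), ("test", test)):
            for vol, mask in items:
                vp = out_dir / split / f"{vol.subject_id}.nii.gz"
                mp = out_dir / split / f"{vol.subject_id}_mask.nii.gz"
                write_volume(vol, vp)
                write_mask(mask, mp, spacing=vol.spacing)
                manifest[split].append(
                    {"subject_id": vol.subject_id, "volume": str(vp.name), "mask": str(mp.name)}
                )
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return train, test
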
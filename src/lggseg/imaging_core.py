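"""Core imaging types and I/O for the segmentation pipeline.

A study volume is a single-channel 3D grid of scalar intensities indexed
``(slice, row, col)`` with anisotropic voxel spacing (slice spacing is
typically coarser than in-plane pixel width, e.g. 2 mm vs 0.47 mm for the
T2-FLAIR acquisitions this pipeline targets).  Binary masks share the grid
and convention; ``1`` marks tumor.  Score maps are the strided two-class
probability grids produced by dense CNN inference, upsampled back to full
resolution with a bicubic convolution kernel before CRF refinement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "ScoreMap",
    "DEFAULT_SPACING",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "upsample_scores",
    "bicubic_resize",
]

#: (slice spacing, pixel height, pixel width) in millimetres, used when a
#: slice-stack input carries no geometry of its own.
DEFAULT_SPACING = (2.0, 0.47, 0.47)


@dataclass
class Volume:
    """Single-channel 3D intensity grid with voxel spacing metadata.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Scalar intensities in acquisition units.  Integer input is
        converted to float64 on construction.
    spacing : tuple of float
        ``(slice_spacing, pixel_height, pixel_width)`` in mm.
    subject_id : str
        Opaque identifier carried through the pipeline.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")
        # 16-bit (or any integer) acquisitions are promoted immediately:
        # normalization produces signed values.
        if not np.issubdtype(self.voxels.dtype, np.floating):
            self.voxels = self.voxels.astype(np.float64)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """Copy of this volume with new voxel data, same geometry."""
        return Volume(voxels, spacing=self.spacing, subject_id=self.subject_id)


@dataclass
class BinaryMask:
    """A {0,1} label grid aligned with a :class:`Volume`; 1 = tumor."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.labels.shape}")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_aligned(self, volume: Volume) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


@dataclass
class ScoreMap:
    """Per-slice two-class probabilities at spatial stride ``stride``.

    ``probs`` has shape ``(rows_s, cols_s, 2)`` with channel 0 = background
    and channel 1 = tumor; each pixel's channels sum to 1.  ``origin`` is
    the full-resolution (row, col) coordinate of score sample (0, 0) —
    patch-classification networks with a 33-px receptive field score
    centres starting at 16.
    """

    probs: np.ndarray
    stride: int = 4
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[-1] != 2:
            raise ValueError(f"score map must be (H, W, 2), got {self.probs.shape}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel channel sums must equal 1 within 1e-6")


# ---------------------------------------------------------------------------
# I/O


def _read_stack(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an ordered PNG/TIFF slice stack described by a manifest.

    ``path`` is either a ``manifest.json`` file or a directory containing
    one.  The manifest lists slice files in order and optionally a spacing.
    """
    import imageio.v3 as iio

    if path.is_dir():
        manifest_path = path / "manifest.json"
    else:
        manifest_path = path
    if not manifest_path.exists():
        raise IOError(f"stack manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    spacing = tuple(manifest.get("spacing", DEFAULT_SPACING))
    base = manifest_path.parent
    slices = []
    shape0 = None
    for name in manifest["slices"]:
        fp = base / name
        if not fp.exists():
            raise IOError(f"missing slice file: {fp}")
        arr = np.asarray(iio.imread(fp))
        if arr.ndim == 3:  # collapse any color axis; stacks are greyscale
            arr = arr[..., 0]
        if shape0 is None:
            shape0 = arr.shape
        elif arr.shape != shape0:
            raise IOError(
                f"inconsistent stack dimensions: slice '{name}' has shape "
                f"{arr.shape}, expected {shape0}"
            )
        slices.append(arr)
    if not slices:
        raise IOError(f"stack manifest lists no slices: {manifest_path}")
    return np.stack(slices, axis=0), spacing


def read_volume(path, format: str | None = None, subject_id: str | None = None) -> Volume:
    """Read a volume from NIfTI or an ordered image-slice stack.

    Parameters
    ----------
    path : path-like
        A ``.nii``/``.nii.gz`` file, or a directory / manifest.json of an
        ordered PNG/TIFF slice stack.
    format : {"nifti", "image_stack"}, optional
        Inferred from the path when omitted.
    """
    import nibabel as nib

    path = Path(path)
    if format is None:
        format = "nifti" if path.suffix in (".nii", ".gz") else "image_stack"
    if format == "nifti":
        if not path.exists():
            raise IOError(f"no such file: {path}")
        img = nib.load(str(path))
        # nibabel axes are (x, y, z); pipeline convention is (slice, row, col)
        data = np.asanyarray(img.dataobj).T
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        if any(s <= 0 for s in spacing):
            spacing = DEFAULT_SPACING
    elif format == "image_stack":
        data, spacing = _read_stack(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Volume(data, spacing=spacing, subject_id=subject_id or path.stem.split(".")[0])


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI, preserving spacing metadata."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    img = nib.Nifti1Image(volume.voxels.T, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    """Read a 0/1 mask stored as NIfTI (any integer dtype, nonzero = 1)."""
    vol = read_volume(path, format="nifti")
    return BinaryMask((vol.voxels > 0.5).astype(np.uint8))


def write_mask(mask: BinaryMask, path, spacing: Sequence[float] = DEFAULT_SPACING) -> None:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.uint8).T, affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Bicubic upsampling of score maps


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys bicubic convolution kernel (a = -0.5, the classical choice)."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _bicubic_1d(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample ``values`` along its first axis at fractional ``coords``.

    Uses the 4-tap Keys kernel with edge replication: out-of-range taps
    are clamped to the boundary sample.
    """
    n = values.shape[0]
    base = np.floor(coords).astype(int)
    frac = coords - base
    out = np.zeros((coords.shape[0],) + values.shape[1:], dtype=np.float64)
    for k in range(-1, 3):
        idx = np.clip(base + k, 0, n - 1)
        w = _keys_kernel(frac - k)
        out += w.reshape((-1,) + (1,) * (values.ndim - 1)) * values[idx]
    return out


def bicubic_resize(channel: np.ndarray, coords_r: np.ndarray, coords_c: np.ndarray) -> np.ndarray:
    """Separable Keys-bicubic sampling of a 2D array at a coordinate grid."""
    tmp = _bicubic_1d(channel, coords_r)  # (len(coords_r), W)
    tmp = _bicubic_1d(tmp.T, coords_c)  # (len(coords_c), len(coords_r))
    return tmp.T


def upsample_scores(scores: ScoreMap, target_shape: tuple[int, int]) -> np.ndarray:
    """Upsample a strided score map to full resolution by bicubic interpolation.

    The CNN's dense output is ``stride`` times smaller than the image; the
    score grid is interpolated back with the bicubic convolution kernel,
    clipped to [0, 1] and renormalized so the two channels sum to 1.

    Parameters
    ----------
    scores : ScoreMap
    target_shape : (rows, cols)
        Full-resolution shape; must be within one stride of
        ``stride * score_shape`` (plus the origin offset).

    Returns
    -------
    ndarray, shape (rows, cols, 2)
    """
    h, w, _ = scores.probs.shape
    if h < 1 or w < 1:
        raise ValueError("empty score map")
    H, W = target_shape
    s = scores.stride
    cover_h = scores.origin[0] * 2 + (h - 1) * s + 1
    cover_w = scores.origin[1] * 2 + (w - 1) * s + 1
    if abs(H - cover_h) > 2 * s or abs(W - cover_w) > 2 * s:
        raise ValueError(
            f"target shape {target_shape} incompatible with score grid "
            f"{(h, w)} at stride {s} and origin {scores.origin}"
        )
    # full-resolution pixel r maps to score-grid coordinate (r - origin)/s
    coords_r = (np.arange(H) - scores.origin[0]) / s
    coords_c = (np.arange(W) - scores.origin[1]) / s
    out = np.empty((H, W, 2), dtype=np.float64)
    for ch in range(2):
        out[..., ch] = bicubic_resize(scores.probs[..., ch], coords_r, coords_c)
    out = np.clip(out, 0.0, 1.0)
    denom = out.sum(axis=-1, keepdims=True)
    # a pixel clipped to (0, 0) is maximally uncertain
    np.divide(out, denom, out=out, where=denom > 0)
    out[denom[..., 0] == 0] = 0.5
    return out
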
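"""High-level orchestration: train, segment, evaluate.

Thin glue over the stage modules so the CLI, tests and scripted
experiments share one code path: normalization statistics are fitted on
the training cohort only and reused everywhere downstream.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .cnn import NetworkSpec, PatchCNN, TrainConfig, TrainHistory, build_network, dense_inference, train
from .densecrf import CRFParams, refine_volume
from .imaging_core import BinaryMask, ScoreMap, Volume, upsample_scores
from .metrics import cohort_summary, evaluate_masks
from .postprocess import DEFAULT_MIN_AREA, postprocess_mask
from .preprocess import NormStats, apply_normalizer, fit_normalizer
from .sampler import build_training_set

__all__ = ["TrainedModel", "SegmentationResult", "train_pipeline", "score_volume",
           "raw_cnn_mask", "segment_volume", "evaluate_cohort"]


@dataclass
class TrainedModel:
    model: PatchCNN
    stats: NormStats
    history: TrainHistory


@dataclass
class SegmentationResult:
    mask: BinaryMask  # after CRF + morphology
    raw_mask: BinaryMask  # thresholded CNN scores, no CRF
    score_maps: list[ScoreMap]
    timings: dict = field(default_factory=dict)


def train_pipeline(
    cohort: list[tuple[Volume, BinaryMask]],
    spec: NetworkSpec,
    config: TrainConfig,
    n_per_slice: int = 50,
    tumor_fraction: float = 0.4,
    max_patches: int | None = None,
) -> TrainedModel:
    """Fit normalization on the cohort, sample patches, train the CNN."""
    stats = fit_normalizer([v for v, _ in cohort])
    patches = build_training_set(
        cohort,
        stats=stats,
        n_per_slice=n_per_slice,
        tumor_fraction=tumor_fraction,
        channels=spec.in_channels,
        seed=config.seed,
    )
    if max_patches is not None and len(patches) > max_patches:
        patches.windows = patches.windows[:max_patches]
        patches.centers = patches.centers[:max_patches]
        patches.labels = patches.labels[:max_patches]
    model = build_network(spec, seed=config.seed, dropout_rate=config.dropout_rate)
    history = train(model, patches, config)
    return TrainedModel(model, stats, history)


def score_volume(tm: TrainedModel, volume: Volume) -> list[ScoreMap]:
    """Dense-score a raw volume (normalized with the training stats)."""
    return dense_inference(tm.model, apply_normalizer(volume, tm.stats))


def raw_cnn_mask(score_maps: list[ScoreMap], shape: tuple[int, int, int]) -> BinaryMask:
    """Upsampled, thresholded CNN scores with no CRF (ablation baseline)."""
    out = np.zeros(shape, dtype=np.uint8)
    for z, sm in enumerate(score_maps):
        probs = upsample_scores(sm, shape[1:])
        out[z] = (probs[..., 1] > probs[..., 0]).astype(np.uint8)
    return BinaryMask(out)


def segment_volume(
    tm: TrainedModel,
    volume: Volume,
    crf_params: CRFParams | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    skip_crf: bool = False,
    crf_mode: str = "filtered",
) -> SegmentationResult:
    """Full segmentation of one volume: CNN -> CRF -> morphology."""
    timings = {}
    t0 = time.perf_counter()
    score_maps = score_volume(tm, volume)
    timings["cnn"] = time.perf_counter() - t0
    raw = raw_cnn_mask(score_maps, volume.shape)
    if skip_crf:
        return SegmentationResult(raw, raw, score_maps, timings)
    params = crf_params or CRFParams()
    t0 = time.perf_counter()
    refined = refine_volume(score_maps, volume, params, mode=crf_mode)
    timings["crf"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    final = postprocess_mask(refined, min_area=min_area)
    timings["postprocess"] = time.perf_counter() - t0
    return SegmentationResult(final, raw, score_maps, timings)


def evaluate_cohort(pairs: list[tuple[BinaryMask, BinaryMask, str]]):
    """Per-subject metric rows + summary for (pred, truth, id) triples."""
    rows = [evaluate_masks(p, t, subject_id=sid) for p, t, sid in pairs]
    return rows, cohort_summary(rows)
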
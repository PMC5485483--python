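"""Coordinate-sweep tuning of CRF parameters on a training cohort.

Four parameters are searched over discretized inclusive ranges (omega1,
sigma_alpha, sigma_beta, iterations); omega2 and sigma_gamma are held
fixed.  Starting from a random grid point, one pass visits the
parameters in order and, for each, evaluates every candidate value with
the others held at their incumbents, retaining the best — so the total
number of objective evaluations is exactly the sum of the candidate-list
lengths (27 for the default grid: 2 + 11 + 8 + 6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .densecrf import CRFParams, refine_volume
from .imaging_core import BinaryMask, ScoreMap, Volume
from .metrics import confusion, dsc

__all__ = ["ParamGrid", "parse_range", "coordinate_sweep", "tune", "DEFAULT_GRID_STRINGS"]

#: searched parameters, in sweep (column) order, with their default ranges
DEFAULT_GRID_STRINGS = {
    "omega1": "5:5:10",
    "sigma_alpha": "20:5:70",
    "sigma_beta": "3:1:10",
    "iterations": "5:1:10",
}
SWEEP_ORDER = ("omega1", "sigma_alpha", "sigma_beta", "iterations")
DEFAULT_FIXED = {"omega2": 5.0, "sigma_gamma": 5.0}


def parse_range(spec: str) -> list[float]:
    """Parse an inclusive ``start:step:stop`` range string into values.

    ``"20:5:70"`` gives the 11 values 20, 25, ..., 70; the stop value is
    included when ``stop - start`` is a multiple of ``step``.
    """
    parts = str(spec).split(":")
    if len(parts) != 3:
        raise ValueError(f"malformed range {spec!r}; expected 'start:step:stop'")
    try:
        a, s, b = (float(p) for p in parts)
    except ValueError as e:
        raise ValueError(f"malformed range {spec!r}: {e}") from None
    if s <= 0:
        raise ValueError(f"range step must be > 0, got {s}")
    if a > b:
        raise ValueError(f"range start {a} exceeds stop {b}")
    n = int(np.floor((b - a) / s + 1e-9)) + 1
    vals = [a + i * s for i in range(n)]
    return vals


@dataclass
class ParamGrid:
    """Candidate value lists for the four searched CRF parameters."""

    omega1: list[float]
    sigma_alpha: list[float]
    sigma_beta: list[float]
    iterations: list[float]

    def __post_init__(self) -> None:
        for name in SWEEP_ORDER:
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"empty candidate list for {name}")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"candidates for {name} must be strictly increasing")

    @classmethod
    def from_strings(cls, ranges: dict[str, str] | None = None) -> "ParamGrid":
        ranges = {**DEFAULT_GRID_STRINGS, **(ranges or {})}
        return cls(**{name: parse_range(ranges[name]) for name in SWEEP_ORDER})

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(getattr(self, name)) for name in SWEEP_ORDER)

    @property
    def n_evaluations(self) -> int:
        return sum(self.counts)


@dataclass
class SweepLogEntry:
    param: str
    value: float
    params: CRFParams
    score: float


def _make_params(incumbent: dict[str, float], fixed: dict[str, float]) -> CRFParams:
    return CRFParams(
        omega1=incumbent["omega1"],
        omega2=fixed["omega2"],
        sigma_alpha=incumbent["sigma_alpha"],
        sigma_beta=incumbent["sigma_beta"],
        sigma_gamma=fixed["sigma_gamma"],
        iterations=int(incumbent["iterations"]),
    )


def coordinate_sweep(
    grid: ParamGrid,
    objective: Callable[[CRFParams], float],
    fixed: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[CRFParams, list[SweepLogEntry]]:
    """Single-pass coordinate sweep maximizing ``objective`` over the grid.

    A random initial grid point is drawn with ``seed``; then each
    parameter in turn is scanned over all its candidates (including the
    incumbent value) with the others held fixed, keeping the best.  Ties
    go to the smaller value (candidates are scanned in increasing
    order and only strict improvements replace the incumbent).

    Returns the winning parameters and the full evaluation log; the log
    length equals ``grid.n_evaluations`` exactly.
    """
    fixed = {**DEFAULT_FIXED, **(fixed or {})}
    rng = np.random.default_rng(seed)
    incumbent = {
        name: getattr(grid, name)[rng.integers(len(getattr(grid, name)))]
        for name in SWEEP_ORDER
    }
    log: list[SweepLogEntry] = []
    for name in SWEEP_ORDER:
        scan_best, scan_value = -np.inf, None
        for value in getattr(grid, name):
            trial = dict(incumbent)
            trial[name] = value
            params = _make_params(trial, fixed)
            try:
                score = float(objective(params))
            except Exception as e:
                raise RuntimeError(f"objective failed at {params}: {e}") from e
            log.append(SweepLogEntry(name, value, params, score))
            # candidates scanned in increasing order; strict improvement
            # only, so ties resolve to the smaller value
            if score > scan_best:
                scan_best, scan_value = score, value
        incumbent[name] = scan_value
    return _make_params(incumbent, fixed), log


def tune(
    cohort: list[tuple[Volume, BinaryMask, list[ScoreMap]]],
    grid: ParamGrid | None = None,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
    mode: str = "filtered",
    return_log: bool = False,
):
    """Tune CRF parameters to maximize mean DSC over a training cohort.

    Each cohort entry is (volume, ground-truth mask, per-slice score
    maps); the objective refines every subject with the candidate
    parameters and averages the Dice coefficients (unweighted).
    """
    if not cohort:
        raise ValueError("empty cohort")
    grid = grid or ParamGrid.from_strings()

    def objective(params: CRFParams) -> float:
        scores = []
        for vol, truth, smaps in cohort:
            pred = refine_volume(smaps, vol, params, mode=mode)
            scores.append(dsc(confusion(pred, truth)))
        return float(np.mean(scores))

    best, log = coordinate_sweep(grid, objective, fixed=fixed, seed=seed)
    return (best, log) if return_log else best


def sweep_log_to_frame(log: list[SweepLogEntry]):
    """Evaluation log as a DataFrame (one row per objective call)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "param": e.param,
                "value": e.value,
                "omega1": e.params.omega1,
                "omega2": e.params.omega2,
                "sigma_alpha": e.params.sigma_alpha,
                "sigma_beta": e.params.sigma_beta,
                "sigma_gamma": e.params.sigma_gamma,
                "iterations": e.params.iterations,
                "score": e.score,
            }
            for e in log
        ]
    )
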
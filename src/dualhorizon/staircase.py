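"""Adaptive 4-2-1 staircase for threshold estimation, plus a constant-stimuli
oracle for validating it.

The staircase tracks the unsigned eccentricity |IR| of ellipses of one axis
(horizontal ellipses carry +|IR|, vertical ones -|IR|). A correct
categorisation of the ellipse moves the level one step down; any other
response (circle or the wrong axis) moves it one step up, so the procedure
converges on the 50% point of the psychometric function. The step magnitude
shrinks 4 -> 2 -> 1 IR% as reversals accumulate, and the threshold estimate
is the mean of the final reversal levels.

``constant_stimuli_estimate`` is an independent method-of-constant-stimuli
oracle: it simulates a fixed grid of levels and fits a cumulative-normal
psychometric function to P(correct) by probit maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .encoding import CalibrationMap, TorsionEncoder, get_calibration
from .errors import GridMisspecificationError, InvalidParameterError
from .observer import Axis, ObserverParams, classify
from .torsion import TorsionState


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the 4-2-1 adaptive procedure (all in IR %)."""

    start_ir: float = 12.0
    step_sequence: tuple[float, ...] = (4.0, 2.0, 1.0)
    reversals_per_step: int = 2
    total_reversals: int = 16
    max_trials: int = 120
    reversal_average_count: int = 10
    ir_floor: float = 0.25
    ir_cap: float = 60.0

    def __post_init__(self) -> None:
        if self.start_ir <= max(self.step_sequence):
            raise InvalidParameterError(
                "start_ir must exceed the largest step "
                f"({self.start_ir} <= {max(self.step_sequence)})"
            )
        if self.total_reversals < 1 or self.max_trials < 1:
            raise InvalidParameterError("reversal/trial counts must be positive")
        if not 0 < self.ir_floor < self.ir_cap:
            raise InvalidParameterError("require 0 < ir_floor < ir_cap")


@dataclass(frozen=True)
class ThresholdEstimate:
    """An IR% discrimination threshold for one axis/eye/procedure."""

    axis: Axis
    ir_threshold: float
    n_trials: int
    reversal_values: list[float] = field(default_factory=list)
    converged: bool = True
    trial_log: pd.DataFrame | None = None


def _encoder_for(
    torsion: TorsionState, calib: CalibrationMap | None
) -> TorsionEncoder:
    if calib is None:
        calib = get_calibration()
    return TorsionEncoder(torsion, calib)


def run_staircase(
    axis: Axis,
    torsion: TorsionState,
    params: ObserverParams,
    config: StaircaseConfig = StaircaseConfig(),
    noise_source: np.random.Generator | None = None,
    calib: CalibrationMap | None = None,
) -> ThresholdEstimate:
    """Run one 4-2-1 staircase and estimate the threshold.

    One-down after a correct categorisation of the ellipse, one-up after any
    other response. The estimate is the mean of the last
    ``reversal_average_count`` reversal levels; if ``max_trials`` elapses
    before ``total_reversals`` reversals the estimate is returned with
    ``converged=False``. Identical seeds give identical trial logs.
    """
    if noise_source is None:
        raise InvalidParameterError("run_staircase requires a seeded noise_source")
    enc = _encoder_for(torsion, calib)
    sign = 1.0 if axis == "horizontal" else -1.0

    level = float(config.start_ir)
    last_direction = 0
    reversals: list[float] = []
    rows: list[dict] = []

    for trial in range(config.max_trials):
        percept = enc.perceived(sign * level)
        noisy = percept + params.sigma * noise_source.standard_normal()
        if params.lapse_rate > 0 and noise_source.random() < params.lapse_rate:
            response = ("circle", "horizontal", "vertical")[
                noise_source.integers(3)
            ]
        else:
            response = classify(noisy, params.criterion)
        correct = response == axis
        direction = -1 if correct else +1
        is_reversal = last_direction != 0 and direction != last_direction
        if is_reversal:
            reversals.append(level)
        step = config.step_sequence[
            min(len(reversals) // config.reversals_per_step,
                len(config.step_sequence) - 1)
        ]
        rows.append(
            {
                "trial": trial,
                "presented_ir": sign * level,
                "axis": axis,
                "response": response,
                "correct": correct,
                "step_size": step,
                "reversal_flag": is_reversal,
            }
        )
        if len(reversals) >= config.total_reversals:
            break
        level = float(
            np.clip(level + direction * step, config.ir_floor, config.ir_cap)
        )
        last_direction = direction

    converged = len(reversals) >= config.total_reversals
    if reversals:
        tail = reversals[-config.reversal_average_count:]
        estimate = float(np.mean(tail))
    else:
        estimate = level
    return ThresholdEstimate(
        axis=axis,
        ir_threshold=estimate,
        n_trials=len(rows),
        reversal_values=reversals,
        converged=converged,
        trial_log=pd.DataFrame(rows),
    )


def replay_staircase(
    correct_sequence: list[bool], config: StaircaseConfig = StaircaseConfig()
) -> list[float]:
    """Reconstruct the presented |IR| levels from the correctness sequence.

    Audit helper: the staircase is a deterministic state machine given the
    responses, so the levels recomputed here must match the trial log.
    """
    level = float(config.start_ir)
    last_direction = 0
    reversals = 0
    levels: list[float] = []
    for correct in correct_sequence:
        levels.append(level)
        direction = -1 if correct else +1
        if last_direction != 0 and direction != last_direction:
            reversals += 1
        step = config.step_sequence[
            min(reversals // config.reversals_per_step,
                len(config.step_sequence) - 1)
        ]
        if reversals >= config.total_reversals:
            break
        level = float(
            np.clip(level + direction * step, config.ir_floor, config.ir_cap)
        )
        last_direction = direction
    return levels


def constant_stimuli_estimate(
    axis: Axis,
    torsion: TorsionState,
    params: ObserverParams,
    ir_grid: np.ndarray,
    trials_per_level: int,
    noise_source: np.random.Generator | None = None,
    p_target: float = 0.5,
    calib: CalibrationMap | None = None,
) -> ThresholdEstimate:
    """Method-of-constant-stimuli threshold via a probit psychometric fit.

    Simulates ``trials_per_level`` trials at each unsigned level of
    ``ir_grid``, fits ``P(correct) = Phi(b0 + b1 * |IR|)`` by maximum
    likelihood, and returns the level at which the fitted curve crosses
    ``p_target``.

    Raises
    ------
    GridMisspecificationError
        If the grid sits entirely above or below threshold (all-correct or
        all-wrong responses leave the slope unidentifiable), or the fit is
        otherwise degenerate.
    """
    if noise_source is None:
        raise InvalidParameterError(
            "constant_stimuli_estimate requires a seeded noise_source"
        )
    if trials_per_level < 50:
        raise InvalidParameterError(
            f"trials_per_level must be >= 50, got {trials_per_level}"
        )
    levels = np.asarray(ir_grid, dtype=float)
    if levels.ndim != 1 or levels.size < 2 or np.any(levels <= 0):
        raise InvalidParameterError("ir_grid must be >= 2 positive levels")
    enc = _encoder_for(torsion, calib)
    sign = 1.0 if axis == "horizontal" else -1.0

    n_correct = np.empty(levels.size, dtype=float)
    for i, lvl in enumerate(levels):
        mu = enc.perceived(sign * lvl)
        noisy = mu + params.sigma * noise_source.standard_normal(trials_per_level)
        if axis == "horizontal":
            correct = noisy > params.criterion
        else:
            correct = noisy < -params.criterion
        n_correct[i] = np.count_nonzero(correct)

    total = levels.size * trials_per_level
    if n_correct.sum() == 0 or n_correct.sum() == total:
        raise GridMisspecificationError(
            "all responses identical: grid does not straddle the threshold"
        )

    endog = np.column_stack([n_correct, trials_per_level - n_correct])
    exog = sm.add_constant(levels)
    model = sm.GLM(
        endog, exog, family=sm.families.Binomial(link=sm.families.links.Probit())
    )
    try:
        result = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        raise GridMisspecificationError(f"psychometric fit failed: {exc}") from exc
    b0, b1 = result.params
    if not np.isfinite(b1) or b1 <= 0:
        raise GridMisspecificationError(
            f"non-positive psychometric slope ({b1}); grid misspecified"
        )
    threshold = float((norm.ppf(p_target) - b0) / b1)
    if threshold <= 0:
        raise GridMisspecificationError(
            f"fitted threshold {threshold} is non-positive; grid misspecified"
        )
    return ThresholdEstimate(
        axis=axis,
        ir_threshold=threshold,
        n_trials=total,
        reversal_values=[],
        converged=True,
    )
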
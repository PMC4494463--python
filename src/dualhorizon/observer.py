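"""Triple-forced-choice observer: noisy responses, closed-form probabilities
and an analytic threshold oracle.

The observer judges each presentation as "circle", "horizontal" (ellipse) or
"vertical" (ellipse). The decision variable is the perceived IR corrupted by
additive zero-mean Gaussian noise of standard deviation ``sigma``; the circle
category is a symmetric band of half-width ``criterion`` around zero, so

    P(horizontal) = 1 - Phi((criterion - mu) / sigma)
    P(vertical)   = Phi((-criterion - mu) / sigma)

with ``mu`` the deterministic perceived IR. The discrimination threshold for
an axis is the least stimulus eccentricity at which the true category is
reported with probability ``p_target``; because the percept is monotone in
IR this is found by bracketed root solving and serves as the exact oracle
against which the adaptive staircase is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .encoding import CalibrationMap, TorsionEncoder, get_calibration
from .errors import InvalidParameterError, ThresholdOutOfRangeError
from .stimuli import EllipseStimulus
from .torsion import DEFAULT_VLAMBDA_GAIN, TorsionState

Category = Literal["circle", "horizontal", "vertical"]
Axis = Literal["horizontal", "vertical"]

CATEGORIES: tuple[Category, ...] = ("circle", "horizontal", "vertical")

#: Eccentricity cap used by the analytic threshold search, IR %.
IR_SEARCH_CAP = 60.0


@dataclass(frozen=True)
class ObserverParams:
    """Internal-noise, criterion and torsion-gain parameters of one observer.

    Parameters
    ----------
    sigma
        Standard deviation of the additive perceptual noise, IR %.
    criterion
        Half-width of the "circle" response band, IR %.
    gain
        V_lambda gain, per degree of torsion.
    lapse_rate
        Probability of a uniformly random response regardless of the
        percept (0 by default; the task model assumes an attentive observer).
    """

    sigma: float = 2.0
    criterion: float = 3.0
    gain: float = DEFAULT_VLAMBDA_GAIN
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.criterion < 0:
            raise InvalidParameterError(
                f"criterion must be >= 0, got {self.criterion}"
            )
        if self.gain < 0:
            raise InvalidParameterError(f"gain must be >= 0, got {self.gain}")
        if not 0 <= self.lapse_rate < 1:
            raise InvalidParameterError(
                f"lapse_rate must be in [0, 1), got {self.lapse_rate}"
            )


def classify(noisy_percept: float, criterion: float) -> Category:
    """Partition a noisy percept into the three response categories.

    Horizontal if the percept exceeds +criterion, vertical if below
    -criterion, circle otherwise (boundary equality counts as circle).
    """
    if noisy_percept > criterion:
        return "horizontal"
    if noisy_percept < -criterion:
        return "vertical"
    return "circle"


def _percept(
    stimulus: EllipseStimulus,
    torsion: TorsionState,
    calib: CalibrationMap | None,
) -> float:
    from .encoding import perceived_ir

    if calib is None:
        calib = get_calibration(size=stimulus.size)
    return perceived_ir(stimulus, torsion, calib)


def respond(
    stimulus: EllipseStimulus,
    torsion: TorsionState,
    params: ObserverParams,
    noise_source: np.random.Generator,
    calib: CalibrationMap | None = None,
) -> Category:
    """One trial: perceive, add noise, categorise.

    ``noise_source`` must be an explicitly seeded Generator; an identical
    seed reproduces the response sequence exactly.
    """
    percept = _percept(stimulus, torsion, calib)
    noisy = percept + params.sigma * noise_source.standard_normal()
    if params.lapse_rate > 0 and noise_source.random() < params.lapse_rate:
        return CATEGORIES[noise_source.integers(len(CATEGORIES))]
    return classify(noisy, params.criterion)


def response_probabilities(
    stimulus: EllipseStimulus,
    torsion: TorsionState,
    params: ObserverParams,
    calib: CalibrationMap | None = None,
) -> dict[Category, float]:
    """Exact normal-model probabilities of the three categories (sum to 1)."""
    mu = _percept(stimulus, torsion, calib)
    p_h = 1.0 - norm.cdf((params.criterion - mu) / params.sigma)
    p_v = norm.cdf((-params.criterion - mu) / params.sigma)
    probs = {"circle": 1.0 - p_h - p_v, "horizontal": p_h, "vertical": p_v}
    if params.lapse_rate > 0:
        lam = params.lapse_rate
        probs = {k: (1 - lam) * p + lam / 3.0 for k, p in probs.items()}
    return probs


def p_response(
    category: Category,
    stimulus: EllipseStimulus,
    torsion: TorsionState,
    params: ObserverParams,
    calib: CalibrationMap | None = None,
) -> float:
    """Probability that one trial elicits ``category``."""
    return response_probabilities(stimulus, torsion, params, calib)[category]


def _p_correct_fn(
    axis: Axis,
    encoder: TorsionEncoder,
    params: ObserverParams,
):
    """P(true-category response) as a function of the unsigned eccentricity."""
    sign = 1.0 if axis == "horizontal" else -1.0

    def p_correct(magnitude: float) -> float:
        mu = encoder.perceived(sign * magnitude)
        if axis == "horizontal":
            p = 1.0 - norm.cdf((params.criterion - mu) / params.sigma)
        else:
            p = norm.cdf((-params.criterion - mu) / params.sigma)
        if params.lapse_rate > 0:
            p = (1 - params.lapse_rate) * p + params.lapse_rate / 3.0
        return p

    return p_correct


def analytic_threshold(
    axis: Axis,
    torsion: TorsionState,
    params: ObserverParams,
    p_target: float = 0.5,
    calib: CalibrationMap | None = None,
    encoder: TorsionEncoder | None = None,
) -> float:
    """Closed-form discrimination threshold: least |IR| with P(correct) >= p_target.

    Found by monotone root bracketing on the calibrated percept function.

    Raises
    ------
    ThresholdOutOfRangeError
        If the target performance is unreachable below |IR| = 60.
    InvalidParameterError
        If ``p_target`` is not in (0, 1).
    """
    if not 0.0 < p_target < 1.0:
        raise InvalidParameterError(f"p_target must be in (0, 1), got {p_target}")
    if encoder is None:
        if calib is None:
            calib = get_calibration()
        encoder = TorsionEncoder(torsion, calib)
    p_correct = _p_correct_fn(axis, encoder, params)
    lo, hi = 1e-9, IR_SEARCH_CAP
    if p_correct(hi) < p_target:
        raise ThresholdOutOfRangeError(
            f"P(correct) at |IR|={hi} is below p_target={p_target} "
            f"(axis={axis}, lambda={torsion.lambda_deg})"
        )
    if p_correct(lo) >= p_target:
        return lo
    return float(brentq(lambda t: p_correct(t) - p_target, lo, hi, xtol=1e-8))
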
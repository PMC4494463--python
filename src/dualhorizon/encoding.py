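"""Antagonistic V/H pool activation and the calibrated percept readout.

Model
-----
Each boundary detector of the proximal stimulus carries a spatial-relationship
(SR) coding weight for each of the two antagonistic cortical pools that
analyse aspect ratio: a vertical-pool weight ``s_v = |sin(phi_r)|`` and a
horizontal-pool weight ``s_h = |cos(phi_r)|``, where ``phi_r`` is the
detector's angular position relative to the *retinal* horizon. The pool
drives are radius-weighted sums over the boundary:

    v_act = sum_i  radius_i * max(0, s_v(phi_r_i) + V_lambda)
    h_act = sum_i  radius_i * s_h(phi_r_i)                      (v_only mode)

(numerically, each detector's weight is averaged over the boundary arc it
represents, which keeps the sums stable under detector-count changes).

Torsion enters twice: it rotates the detector angles from the spatial to the
retinal frame (a purely geometric, sign-symmetric effect, negligible at
clinical angles), and it adds the signed offset ``V_lambda = gain * lambda``
to the SR weights -- positive under incyclotorsion (V-pool hyperactivation),
negative under excyclotorsion. In ``symmetric`` mode the offset is also
subtracted from the H-weights, the "alternatively, hyperactivation of the
H-pool" reading; both weights are clipped at zero.

Readout
-------
The percept is obtained by inverting the *untorted* encoder: a calibration
map from the log activation ratio ``log(h_act / v_act)`` to signed IR is
built once at lambda = 0 over a dense IR grid, which enforces isotropy (at
zero torsion the perceived IR equals the true IR by construction). Torsion
then shifts the activation ratio, and the same map converts that shift into
a biased percept: incyclotorsion drives the percept vertical (below the true
IR), excyclotorsion horizontal.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DegenerateEncodingError, ModelMisconfigurationError
from .stimuli import (
    DEFAULT_N_DETECTORS,
    DEFAULT_SIZE_ARCMIN,
    BoundarySample,
    EllipseStimulus,
    boundary_elevations,
    sample_boundary,
    stimulus_from_ir,
)
from .torsion import TorsionState, rotate_to_retinal

#: IR grid on which the lambda=0 calibration is built, percent.
CALIB_IR_MIN = -60.0
CALIB_IR_MAX = 60.0
CALIB_IR_STEP = 0.1

_H_ACT_FLOOR = 1e-9

OFFSET_MODES = ("v_only", "symmetric")


@dataclass(frozen=True)
class PoolActivation:
    """Summed V-pool and H-pool drive for one stimulus presentation."""

    v_act: float
    h_act: float

    @property
    def log_ratio(self) -> float:
        """log(h_act / v_act): the quantity the percept readout inverts."""
        return float(np.log(self.h_act / self.v_act))


def base_sr_value(phi_r: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Untorted SR-coding weights of a detector at retinal elevation phi_r.

    Returns ``(s_v, s_h) = (|sin phi_r|, |cos phi_r|)``; the two weights
    satisfy ``s_v**2 + s_h**2 == 1``. A detector on the retinal horizon
    feeds only the H-pool; one on the vertical meridian only the V-pool.
    """
    return np.abs(np.sin(phi_r)), np.abs(np.cos(phi_r))


#: Midpoint subsamples per detector arc when averaging the SR weights.
_ARC_SUBSAMPLES = 16


def _pool_weights(
    theta_r: np.ndarray,
    v_lambda: float,
    offset_mode: str,
    spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-averaged pool weights of each detector.

    A detector stands for an arc of width ``spacing`` on the boundary, so
    its weight is the average of the clipped SR value over that arc (16
    midpoint subsamples). Point evaluation would make the zero-clipping
    kink near the horizon jump between detector grids, leaving the pool
    sums sensitive to detector count at the 1e-3 IR% level.
    """
    if offset_mode not in OFFSET_MODES:
        raise ModelMisconfigurationError(
            f"offset_mode must be one of {OFFSET_MODES}, got {offset_mode!r}"
        )
    offsets = (np.arange(_ARC_SUBSAMPLES) + 0.5) / _ARC_SUBSAMPLES - 0.5
    theta = theta_r[:, None] + spacing * offsets[None, :]
    s_v, s_h = base_sr_value(theta)
    w_v = np.maximum(0.0, s_v + v_lambda).mean(axis=1)
    if offset_mode == "symmetric":
        w_h = np.maximum(0.0, s_h - v_lambda).mean(axis=1)
    else:
        w_h = s_h.mean(axis=1)
    return w_v, w_h


def pool_activation(
    boundary: BoundarySample,
    torsion: TorsionState,
    offset_mode: str = "v_only",
) -> PoolActivation:
    """Drive of the two cortical pools by a torsion-shifted boundary.

    Raises
    ------
    DegenerateEncodingError
        If the H-pool drive underflows to zero, signalling a torsion/gain
        combination outside the model's validity.
    """
    if boundary.n_detectors == 0:
        raise DegenerateEncodingError("empty boundary sample")
    theta_r = np.asarray(rotate_to_retinal(boundary.elevations, torsion.lambda_deg))
    w_v, w_h = _pool_weights(
        theta_r, torsion.v_lambda, offset_mode, 2.0 * np.pi / boundary.n_detectors
    )
    v_act = float(boundary.radii @ w_v)
    h_act = float(boundary.radii @ w_h)
    if h_act <= _H_ACT_FLOOR:
        raise DegenerateEncodingError(
            f"H-pool drive vanished (lambda={torsion.lambda_deg}, "
            f"gain={torsion.gain}); torsion outside model validity"
        )
    return PoolActivation(v_act=v_act, h_act=h_act)


class CalibrationMap:
    """Strictly-increasing map from log activation ratio to perceived IR (%).

    Built at lambda = 0, so it inverts the untorted encoder exactly on its
    grid: the circle's activation ratio maps to 0 and every grid IR maps to
    itself. Interpolation is monotone cubic (PCHIP), extrapolated linearly
    past the grid ends.
    """

    def __init__(
        self,
        log_ratios: np.ndarray,
        ir_values: np.ndarray,
        size: float,
        n_detectors: int,
    ) -> None:
        diffs = np.diff(log_ratios)
        if not np.all(diffs > 0):
            raise ModelMisconfigurationError(
                "activation log-ratio is not strictly increasing over the IR grid"
            )
        self.log_ratios = log_ratios
        self.ir_values = ir_values
        self.size = size
        self.n_detectors = n_detectors
        self._interp = PchipInterpolator(log_ratios, ir_values, extrapolate=True)

    def __call__(self, log_ratio: np.ndarray | float) -> np.ndarray | float:
        out = self._interp(log_ratio)
        return float(out) if np.isscalar(log_ratio) or np.ndim(log_ratio) == 0 else out

    def to_frame(self):
        """Grid as a pandas DataFrame (columns log_ratio, ir) for audit."""
        import pandas as pd

        return pd.DataFrame({"log_ratio": self.log_ratios, "ir": self.ir_values})

    def to_csv(self, path_or_buf=None) -> str | None:
        if path_or_buf is None:
            buf = StringIO()
            self.to_frame().to_csv(buf, index=False)
            return buf.getvalue()
        self.to_frame().to_csv(path_or_buf, index=False)
        return None


def build_calibration(
    size: float = DEFAULT_SIZE_ARCMIN,
    n_detectors: int = DEFAULT_N_DETECTORS,
    ir_min: float = CALIB_IR_MIN,
    ir_max: float = CALIB_IR_MAX,
    ir_step: float = CALIB_IR_STEP,
) -> CalibrationMap:
    """Build the lambda=0 calibration map over a dense IR grid.

    Raises
    ------
    ModelMisconfigurationError
        If the activation ratio fails to be strictly monotone in IR.
    """
    n_steps = int(round((ir_max - ir_min) / ir_step))
    ir_grid = ir_min + ir_step * np.arange(n_steps + 1)
    untorted = TorsionState(0.0, gain=0.0)
    log_ratios = np.empty_like(ir_grid)
    for i, ir in enumerate(ir_grid):
        boundary = sample_boundary(stimulus_from_ir(float(ir), size), n_detectors)
        log_ratios[i] = pool_activation(boundary, untorted).log_ratio
    return CalibrationMap(log_ratios, ir_grid, size=size, n_detectors=n_detectors)


_calibration_cache: dict[tuple, CalibrationMap] = {}


def get_calibration(
    size: float = DEFAULT_SIZE_ARCMIN, n_detectors: int = DEFAULT_N_DETECTORS
) -> CalibrationMap:
    """Cached default-grid calibration for a given size/detector count."""
    key = (float(size), int(n_detectors))
    if key not in _calibration_cache:
        _calibration_cache[key] = build_calibration(size=size, n_detectors=n_detectors)
    return _calibration_cache[key]


def perceived_ir(
    stimulus: EllipseStimulus,
    torsion: TorsionState,
    calib: CalibrationMap,
    offset_mode: str = "v_only",
) -> float:
    """Perceived signed IR of a stimulus seen through a torted eye.

    Equals the true IR at lambda = 0; lies below it for incyclotorsion
    (vertical bias) and above it for excyclotorsion (horizontal bias).
    """
    boundary = sample_boundary(stimulus, calib.n_detectors)
    act = pool_activation(boundary, torsion, offset_mode)
    return float(calib(act.log_ratio))


class TorsionEncoder:
    """Fast percept evaluator at fixed torsion, size and detector count.

    Precomputes the rotated pool weights once so that evaluating the percept
    of a new IR level costs one polar-radius vector and two dot products --
    the workhorse behind staircase trials and threshold bisection. Results
    are bit-identical to :func:`perceived_ir`.
    """

    def __init__(
        self,
        torsion: TorsionState,
        calib: CalibrationMap,
        offset_mode: str = "v_only",
    ) -> None:
        self.torsion = torsion
        self.calib = calib
        self.offset_mode = offset_mode
        theta_s = boundary_elevations(calib.n_detectors)
        self._cos_sq = np.cos(theta_s) ** 2
        self._sin_sq = np.sin(theta_s) ** 2
        theta_r = rotate_to_retinal(theta_s, torsion.lambda_deg)
        self._w_v, self._w_h = _pool_weights(
            np.asarray(theta_r),
            torsion.v_lambda,
            offset_mode,
            2.0 * np.pi / calib.n_detectors,
        )
        self._size = calib.size
        self._percept_cache: dict[float, float] = {}

    def activation(self, ir: float) -> PoolActivation:
        stim = stimulus_from_ir(ir, self._size)
        a = 0.5 * stim.axis_x
        b = 0.5 * stim.axis_y
        radii = (a * b) / np.sqrt(b * b * self._cos_sq + a * a * self._sin_sq)
        v_act = float(radii @ self._w_v)
        h_act = float(radii @ self._w_h)
        if h_act <= _H_ACT_FLOOR:
            raise DegenerateEncodingError(
                f"H-pool drive vanished (lambda={self.torsion.lambda_deg})"
            )
        return PoolActivation(v_act=v_act, h_act=h_act)

    def perceived(self, ir: float) -> float:
        cached = self._percept_cache.get(ir)
        if cached is None:
            cached = float(self.calib(self.activation(ir).log_ratio))
            self._percept_cache[ir] = cached
        return cached
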
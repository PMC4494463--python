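"""Ellipse/circle stimuli, the interaxis-ratio (IR) measure, and boundary sampling.

The stimulus set of the simulated task is a family of ellipses whose two full
axes lie along the spatial horizontal and vertical. Eccentricity is expressed
as the percent interaxis ratio

    IR(%) = 100 * (axis_x - axis_y) / max(axis_x, axis_y),

so a circle has IR = 0, a horizontal ellipse IR > 0 and a vertical ellipse
IR < 0. Stimulus "size" -- the arithmetic mean of the two full axes -- is held
constant (default 300 arcmin) across IR levels, which makes the map from IR to
axes uniquely invertible.

The retinal projection of a stimulus is represented by a dense, uniformly
spaced sample of its boundary in fovea-centred polar coordinates: the set of
boundary detectors that later drives the antagonistic V/H cortical pools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidIRError, InvalidStimulusError, UndersamplingError

#: Default constant stimulus size: mean of the two full axes, in arcmin.
DEFAULT_SIZE_ARCMIN = 300.0

#: Default number of boundary detectors (1 degree angular spacing).
DEFAULT_N_DETECTORS = 360

_MIN_DETECTORS = 8


@dataclass(frozen=True)
class EllipseStimulus:
    """A distal stimulus: an axis-aligned ellipse in visual space.

    Parameters
    ----------
    axis_x, axis_y
        Full axis lengths in arcmin along the spatial horizontal and
        vertical. Both must be strictly positive.
    """

    axis_x: float
    axis_y: float

    def __post_init__(self) -> None:
        if not (self.axis_x > 0 and self.axis_y > 0):
            raise InvalidStimulusError(
                f"stimulus axes must be positive, got ({self.axis_x}, {self.axis_y})"
            )

    @property
    def size(self) -> float:
        """Mean of the two full axes (the quantity held constant), arcmin."""
        return 0.5 * (self.axis_x + self.axis_y)

    @property
    def ir(self) -> float:
        """Signed interaxis ratio of this stimulus, percent."""
        return compute_ir(self.axis_x, self.axis_y)

    def to_dict(self) -> dict:
        return {"axis_x": self.axis_x, "axis_y": self.axis_y}

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseStimulus":
        return cls(axis_x=float(d["axis_x"]), axis_y=float(d["axis_y"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class BoundarySample:
    """The proximal stimulus: boundary detectors in fovea-centred polar form.

    ``elevations`` are the polar angles of the detectors in the spatial
    frame, strictly increasing over one full turn within (-pi, pi];
    ``radii`` are the ellipse polar radii at those angles, arcmin.
    """

    radii: np.ndarray
    elevations: np.ndarray

    @property
    def n_detectors(self) -> int:
        return int(self.radii.shape[0])

    @property
    def points(self) -> list[tuple[float, float]]:
        """Ordered (radius, elevation) pairs, as plain floats."""
        return [(float(r), float(e)) for r, e in zip(self.radii, self.elevations)]

    @property
    def extent_x(self) -> float:
        """Horizontal extent r_x of the proximal stimulus (full width), arcmin."""
        return float(2.0 * np.max(np.abs(self.radii * np.cos(self.elevations))))

    @property
    def extent_y(self) -> float:
        """Vertical extent r_y of the proximal stimulus (full height), arcmin."""
        return float(2.0 * np.max(np.abs(self.radii * np.sin(self.elevations))))

    def to_dict(self) -> dict:
        return {"radii": self.radii.tolist(), "elevations": self.elevations.tolist()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def compute_ir(axis_x: float, axis_y: float) -> float:
    """Signed percent interaxis ratio of an ellipse.

    ``100 * (axis_x - axis_y) / max(axis_x, axis_y)``: positive for a
    horizontal ellipse, negative for a vertical one, exactly 0 for a circle.

    Raises
    ------
    InvalidStimulusError
        If either axis is non-positive.
    """
    if not (axis_x > 0 and axis_y > 0):
        raise InvalidStimulusError(
            f"stimulus axes must be positive, got ({axis_x}, {axis_y})"
        )
    return 100.0 * (axis_x - axis_y) / max(axis_x, axis_y)


def stimulus_from_ir(ir: float, size: float = DEFAULT_SIZE_ARCMIN) -> EllipseStimulus:
    """The unique ellipse with the given signed IR and constant mean axis.

    Solves ``(axis_x + axis_y)/2 = size`` together with the IR definition;
    ``compute_ir(stimulus_from_ir(ir, s)) == ir`` to 1e-9.

    Raises
    ------
    InvalidIRError
        If ``|ir| >= 100`` (a degenerate, zero-width ellipse).
    InvalidStimulusError
        If ``size <= 0``.
    """
    if abs(ir) >= 100.0:
        raise InvalidIRError(f"|IR| must be < 100, got {ir}")
    if not size > 0:
        raise InvalidStimulusError(f"size must be positive, got {size}")
    # For ir >= 0 the long (focal) axis is horizontal: ax - ay = (ir/100)*ax.
    frac = abs(ir) / 100.0
    long_axis = 2.0 * size / (2.0 - frac)
    short_axis = 2.0 * size - long_axis
    if ir >= 0:
        return EllipseStimulus(axis_x=long_axis, axis_y=short_axis)
    return EllipseStimulus(axis_x=short_axis, axis_y=long_axis)


def ellipse_polar_radius(
    axis_x: float, axis_y: float, theta: np.ndarray | float
) -> np.ndarray | float:
    """Polar radius of an axis-aligned ellipse at polar angle ``theta``.

    With semi-axes a = axis_x/2 and b = axis_y/2:
    ``r(theta) = a*b / sqrt((b*cos(theta))**2 + (a*sin(theta))**2)``.
    """
    a = 0.5 * axis_x
    b = 0.5 * axis_y
    return (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def boundary_elevations(n_detectors: int) -> np.ndarray:
    """Uniform strictly-increasing polar angles covering one turn, in (-pi, pi]."""
    return -np.pi + 2.0 * np.pi * np.arange(1, n_detectors + 1) / n_detectors


def sample_boundary(
    stimulus: EllipseStimulus, n_detectors: int = DEFAULT_N_DETECTORS
) -> BoundarySample:
    """Discretise the stimulus boundary into the proximal detector set.

    Raises
    ------
    UndersamplingError
        If fewer than 8 detectors are requested.
    """
    if n_detectors < _MIN_DETECTORS:
        raise UndersamplingError(
            f"n_detectors must be >= {_MIN_DETECTORS}, got {n_detectors}"
        )
    theta = boundary_elevations(n_detectors)
    radii = ellipse_polar_radius(stimulus.axis_x, stimulus.axis_y, theta)
    return BoundarySample(radii=radii, elevations=theta)
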
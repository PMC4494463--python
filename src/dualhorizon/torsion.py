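"""Spatial vs retinal coordinate frames under bulbar (ocular) torsion.

Cyclotorsion rotates the eye about the line of sight, tilting the retinal
horizontal meridian (the "retinal horizon", anatomically the maculopapillary
axis) away from the true horizontal of visual space (the "spatial horizon").
A detector that sits at elevation phi_s relative to the spatial horizon then
sits at a different elevation phi_r relative to the retinal horizon; the two
differ by a vertical shift whose sign depends on the hemiretina.

Conventions (right eye, configurable by flipping the sign of lambda):

* positive lambda = incyclotorsion (top of the eye rotates nasally),
  negative lambda = excyclotorsion;
* under incyclotorsion the retinal horizon shifts *up* on the temporal side
  and *down* on the nasal side, so the torsion-induced change of a detector's
  spatial-relationship coding value is a single signed scalar
  V_lambda = gain * lambda applied uniformly;
* hemifield is temporal when the detector's spatial horizontal coordinate is
  positive (ties at exactly zero count as temporal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidParameterError

#: Default V_lambda gain, per degree of torsion. Sets the percept sensitivity
#: to roughly 0.8 IR% per degree under the default calibration, which keeps
#: simulated horizontal thresholds positive and in the low single digits
#: across the clinical torsion range (see docs/methods.md).
DEFAULT_VLAMBDA_GAIN = 0.0017

#: Sanity bound on |lambda|: clinical cyclotorsions are small.
MAX_ABS_LAMBDA_DEG = 15.0

Hemifield = Literal["nasal", "temporal"]


@dataclass(frozen=True)
class TorsionState:
    """Signed torsion angle and its derived SR-value offset.

    Parameters
    ----------
    lambda_deg
        Torsion about the line of sight, degrees. Positive = incyclotorsion.
    gain
        Proportionality constant turning degrees of torsion into the
        dimensionless per-detector offset ``v_lambda`` (>= 0).
    """

    lambda_deg: float
    gain: float = DEFAULT_VLAMBDA_GAIN

    def __post_init__(self) -> None:
        if abs(self.lambda_deg) > MAX_ABS_LAMBDA_DEG:
            raise InvalidParameterError(
                f"|lambda_deg| must be <= {MAX_ABS_LAMBDA_DEG}, got {self.lambda_deg}"
            )
        if self.gain < 0:
            raise InvalidParameterError(f"gain must be >= 0, got {self.gain}")

    @property
    def v_lambda(self) -> float:
        """Signed SR-value offset: positive under incyclo, negative under excyclo."""
        return v_lambda_of(self.lambda_deg, self.gain)

    @property
    def lambda_rad(self) -> float:
        return float(np.deg2rad(self.lambda_deg))


@dataclass(frozen=True)
class DetectorPosition:
    """A boundary detector's elevation in both frames, plus its hemifield.

    ``phi_s``/``phi_r`` are signed angular distances (radians) from the
    spatial/retinal horizon, in [-pi/2, pi/2].
    """

    phi_s: float
    phi_r: float
    hemifield: Hemifield


def v_lambda_of(lambda_deg: float, gain: float) -> float:
    """Signed offset V_lambda = gain * lambda collapsing the hemiretina rules.

    Upward shift on the temporal side = downward shift on the nasal side =
    +V_lambda under incyclotorsion; the reverse shifts = -V_lambda under
    excyclotorsion. Both rules reduce to one signed scalar.
    """
    if gain < 0:
        raise InvalidParameterError(f"gain must be >= 0, got {gain}")
    return gain * lambda_deg


def hemifield_of(x_coordinate: float) -> Hemifield:
    """Hemifield of a detector from its spatial horizontal coordinate.

    Right-eye convention: temporal iff x > 0, nasal iff x < 0; exactly 0 is
    assigned temporal (documented tie-break).
    """
    return "temporal" if x_coordinate >= 0 else "nasal"


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-pi, pi]."""
    return np.mod(theta - np.pi, -2.0 * np.pi) + np.pi


def elevation_from_horizon(theta: np.ndarray | float) -> np.ndarray | float:
    """Signed angular distance of a polar angle from the horizontal meridian.

    Positive above the horizon, negative below, in [-pi/2, pi/2]; e.g. a
    polar angle of 178 deg lies 2 deg above the (nasal) horizon.
    """
    return np.arcsin(np.sin(theta))


def rotate_to_retinal(theta_s: np.ndarray | float, lambda_deg: float):
    """Retinal-frame polar angles of spatial-frame angles under torsion.

    The retinal frame is the spatial frame rotated by +lambda, so spatial
    coordinates expressed retinally are rotated by -lambda.
    """
    return wrap_angle(np.asarray(theta_s) - np.deg2rad(lambda_deg))


def to_retinal_frame(
    point: tuple[float, float], lambda_deg: float
) -> DetectorPosition:
    """Express a spatial-frame boundary point in the retinal frame.

    Parameters
    ----------
    point
        ``(radius, polar_angle)`` in the spatial frame, radius > 0 arcmin,
        polar angle in radians.
    lambda_deg
        Torsion angle; positive = incyclotorsion (right eye).

    Returns
    -------
    DetectorPosition
        Elevations from the two horizons and the hemifield label. For
        positive lambda a detector on the spatial horizon in the temporal
        hemifield acquires ``phi_r < 0``: the retinal horizon sits above it.
    """
    radius, theta_s = point
    if not radius > 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    theta_r = float(rotate_to_retinal(theta_s, lambda_deg))
    return DetectorPosition(
        phi_s=float(elevation_from_horizon(theta_s)),
        phi_r=float(elevation_from_horizon(theta_r)),
        hemifield=hemifield_of(radius * np.cos(theta_s)),
    )
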
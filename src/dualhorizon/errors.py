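"""Exception hierarchy for the dual-horizon simulator."""


class DualHorizonError(Exception):
    """Base class for all simulator errors."""


class InvalidStimulusError(DualHorizonError, ValueError):
    """A stimulus axis is non-positive or otherwise unrealisable."""


class InvalidIRError(DualHorizonError, ValueError):
    """Requested interaxis ratio outside the open interval (-100, 100)."""


class UndersamplingError(DualHorizonError, ValueError):
    """Too few boundary detectors to represent the stimulus."""


class InvalidParameterError(DualHorizonError, ValueError):
    """An observer or torsion parameter violates its domain."""


class DegenerateEncodingError(DualHorizonError, ArithmeticError):
    """A cortical pool drive underflowed to zero; torsion outside model validity."""


class ModelMisconfigurationError(DualHorizonError, RuntimeError):
    """The activation-ratio -> IR calibration is not strictly monotone."""


class ThresholdOutOfRangeError(DualHorizonError, RuntimeError):
    """No IR below the eccentricity cap reaches the target performance."""


class GridMisspecificationError(DualHorizonError, RuntimeError):
    """Constant-stimuli grid does not straddle the threshold (degenerate fit)."""


class CohortTooSmallError(DualHorizonError, ValueError):
    """Fewer than three subjects: the correlation is undefined/degenerate."""


class UndefinedCorrelationError(DualHorizonError, ValueError):
    """A correlation input has zero variance."""


class ConfigurationError(DualHorizonError, ValueError):
    """Malformed experiment configuration (carries a field path diagnostic)."""
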
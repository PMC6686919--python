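"""Exception hierarchy shared across the pipeline stages."""


class ReservescanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ReservescanError, ValueError):
    """A parameter outside its documented domain."""


class DegenerateAlignmentError(ReservescanError, ValueError):
    """An alignment too gappy or empty to support the requested operation."""


class ConfigurationError(ReservescanError, ValueError):
    """Missing or inconsistent configuration / input stores."""


class CalibrationError(ReservescanError, RuntimeError):
    """Score distribution unusable for E-value calibration."""


class UncalibratedModelError(ReservescanError, RuntimeError):
    """E-value requested from a model without calibration parameters."""


class IntegrityError(ReservescanError, ValueError):
    """Cross-referenced records that do not agree (unknown ids, duplicates)."""


class InsufficientGroupError(ReservescanError, ValueError):
    """A statistical contrast group with fewer than two members."""
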
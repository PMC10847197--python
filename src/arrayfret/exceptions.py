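"""Exception hierarchy for the arrayfret pipeline."""


class ArrayFretError(Exception):
    """Base class for all package errors."""


class FormatError(ArrayFretError, ValueError):
    """Malformed or inconsistent input data (shapes, counts, columns)."""


class ConfigError(ArrayFretError, ValueError):
    """Invalid or infeasible configuration."""


class DegenerateImageError(ArrayFretError, ValueError):
    """Image unusable for registration (e.g. constant intensity)."""


class RegistrationError(ArrayFretError, RuntimeError):
    """Alignment failure, annotated with the offending section index."""


class CalibrationError(ArrayFretError, ValueError):
    """Bleed-through calibration could not be estimated."""


class SessionMismatchError(ArrayFretError, ValueError):
    """Calibration applied to data from a different imaging session."""


class PlaqueAbsentError(ArrayFretError, ValueError):
    """Distance profiling requested but no plaque was detected."""
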
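"""Exception hierarchy shared across the package."""


class AuxintorError(Exception):
    """Base class for all package-specific errors."""


class SimulationSpecError(AuxintorError, ValueError):
    """A simulator was called with parameters outside its valid domain."""


class ParseError(AuxintorError, ValueError):
    """An input file failed validation; the message names the offending line."""


class AnnotationError(AuxintorError, ValueError):
    """Gene annotation / genome consistency problem."""


class DegeneratePopulationError(AuxintorError, ValueError):
    """A robust scale estimate collapsed to zero, so standardization is undefined."""


class FitFailureError(AuxintorError, RuntimeError):
    """All attempts to fit a model failed."""


class CalibrationError(AuxintorError, ValueError):
    """An isotope-dilution calibration curve is unusable (e.g. non-positive slope)."""
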
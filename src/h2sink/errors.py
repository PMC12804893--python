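"""Exception hierarchy."""


class H2SinkError(Exception):
    """Base class for package errors."""


class InputError(H2SinkError, ValueError):
    """Invalid user-supplied input (values, shapes, units)."""


class CensoredSeriesError(InputError):
    """Too few above-detection-limit points to fit a drawdown."""


class FitError(H2SinkError, RuntimeError):
    """A regression or curve fit could not be performed."""


class NoBracketError(InputError):
    """Observations do not bracket a detection threshold."""


class ConfigurationError(H2SinkError, ValueError):
    """Inconsistent model parameters."""


class CalibrationError(H2SinkError, RuntimeError):
    """Calibration target unreachable within parameter bounds."""


class GenerationError(H2SinkError, ValueError):
    """Synthetic-data spec cannot produce the requested output."""
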
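"""Exception hierarchy shared across the package."""


class NgfcError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NgfcError, ValueError):
    """A parameter set violates its documented constraints."""


class GeometryError(NgfcError, ValueError):
    """Degenerate or inconsistent spatial input."""


class StatisticsError(NgfcError, ValueError):
    """Input unsuitable for the requested statistic (empty, constant, ...)."""


class KineticsError(NgfcError, ValueError):
    """A waveform does not support the requested kinetic measurement."""


class AlignmentError(NgfcError, ValueError):
    """Traces do not share a common time base."""


class InferenceError(NgfcError, RuntimeError):
    """Posterior inference failed or is ill-posed for the given data."""


class CalibrationError(NgfcError, RuntimeError):
    """An optimization loop terminated without reaching its acceptance rule.

    Carries the best parameters found so far in ``best`` when available.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class StabilityError(NgfcError, RuntimeError):
    """Time step too coarse for the fastest configured reaction."""
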
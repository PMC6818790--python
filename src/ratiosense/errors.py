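"""Exception hierarchy shared across ratiosense modules."""


class RatiosenseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RatiosenseError, ValueError):
    """A parameter is outside its mathematical or physical domain."""


class ConfigurationError(RatiosenseError, ValueError):
    """A simulation or analysis configuration is inconsistent or incomplete."""


class CalibrationError(RatiosenseError, RuntimeError):
    """Rate calibration failed (e.g., the search interval does not bracket)."""


class FitError(RatiosenseError, RuntimeError):
    """A model fit did not converge or the data leave it unidentifiable."""


class ValidationError(RatiosenseError, ValueError):
    """Input records violate a structural invariant (e.g., inverted event times)."""
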
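"""Exception hierarchy shared across the package."""


class BnfCurveError(Exception):
    """Base class for all package errors."""


class DomainError(BnfCurveError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UndefinedRauError(DomainError):
    """Ureide and nitrate concentrations are both zero: RAU is 0/0."""


class WeatherGapError(BnfCurveError):
    """The weather series does not cover every day of a requested range."""

    def __init__(self, missing_dates):
        self.missing_dates = list(missing_dates)
        preview = ", ".join(str(d) for d in self.missing_dates[:5])
        more = "" if len(self.missing_dates) <= 5 else f" (+{len(self.missing_dates) - 5} more)"
        super().__init__(f"weather series is missing {len(self.missing_dates)} day(s): {preview}{more}")


class StageOrderError(BnfCurveError):
    """A phenological stage date precedes the thermal-time origin."""


class DegenerateParameterError(DomainError):
    """Curve parameters collapse the model (e.g. t_m == t_max)."""


class InsufficientDataError(BnfCurveError):
    """Too few observations for the requested fit."""


class FitConvergenceError(BnfCurveError):
    """Nonlinear least squares failed to converge.

    Carries the final parameter state so callers can diagnose.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class SchemaError(BnfCurveError):
    """A CSV input violates the expected schema; message carries line numbers."""
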
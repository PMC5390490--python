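"""Exception hierarchy shared by all pipeline stages."""


class PhotolimError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PhotolimError):
    """An input value violates a physical or protocol invariant."""


class SchemaError(PhotolimError):
    """A delimited-text input is missing mandatory columns or is unreadable."""


class InfeasiblePointError(PhotolimError):
    """A record cannot be inverted (e.g. J <= 4(AN+Rd), or Ci <= Cc).

    Such records are flagged and excluded from treatment means rather than
    clipped, because clipping silently biases conductance estimates.
    """


class FitError(PhotolimError):
    """A curve fit failed to converge or is numerically degenerate."""


class CalibrationError(PhotolimError):
    """A densitometry / immunoblot calibration series is unusable."""


class GenerationError(PhotolimError):
    """A synthetic scenario is physically infeasible as configured."""
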
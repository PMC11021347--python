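"""Exception hierarchy shared across the pipeline stages."""


class GlucoclampError(Exception):
    """Base class for all package errors."""


class DomainError(GlucoclampError, ValueError):
    """Input outside the mathematical domain of an operation."""


class IntegrationError(GlucoclampError, RuntimeError):
    """ODE solver failed; carries the solver diagnostic message."""


class AlignmentError(GlucoclampError, ValueError):
    """Simulated and observed series are not on identical time grids."""


class InsufficientDataError(GlucoclampError, ValueError):
    """A series is too short for the requested operation."""


class DegenerateInputError(GlucoclampError, ValueError):
    """Degenerate input (all-zero variable, zero variance, zero integral...)."""


class ConfigError(GlucoclampError, ValueError):
    """Invalid configuration (bad bounds, empty variant family, ...)."""


class IncompleteGridError(GlucoclampError, ValueError):
    """A subject x variant fit grid has missing cells."""
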
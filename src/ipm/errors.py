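"""Exception hierarchy shared by all modules."""


class IPMError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(IPMError):
    """A chain, model or run configuration is inconsistent or incomplete."""


class DomainError(IPMError, ValueError):
    """An input value lies outside its admissible domain."""


class DataError(IPMError):
    """A dataset is too small or malformed for the requested operation."""


class EstimationError(IPMError):
    """A regression model cannot be estimated from the given data."""


class SimulationError(IPMError):
    """A Monte-Carlo cycle produced a non-finite or invalid state."""


class AssessmentError(IPMError):
    """A severity assessment cannot be carried out."""
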
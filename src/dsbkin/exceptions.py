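"""Exception hierarchy for dsbkin."""


class DsbkinError(Exception):
    """Base class for all dsbkin errors."""


class FormatError(DsbkinError, ValueError):
    """A data file does not conform to the expected table format."""


class ValidationError(DsbkinError, ValueError):
    """An input value violates a model or protocol invariant."""


class NumericalError(DsbkinError, RuntimeError):
    """A numerical routine (ODE integrator, optimizer) failed to converge."""


class FitError(DsbkinError, RuntimeError):
    """Model fitting or uncertainty estimation failed."""
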
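"""Exception hierarchy shared across the package."""


class MaldimtuError(Exception):
    """Base class for all package errors."""


class ParseError(MaldimtuError):
    """Malformed input file content."""


class ValidationError(MaldimtuError):
    """A domain object violates its invariants."""


class ParameterError(MaldimtuError):
    """An operation was called with unusable parameters."""


class DegenerateInputError(MaldimtuError):
    """Input is structurally valid but carries no usable signal."""


class FitError(MaldimtuError):
    """A model fit failed to converge or the data are degenerate."""
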
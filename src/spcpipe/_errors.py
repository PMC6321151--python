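"""Exception types shared across the pipeline."""


class SpcPipeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SpcPipeError):
    """A file does not conform to the expected delimited-text layout."""


class ValidationError(SpcPipeError, ValueError):
    """Input values violate a documented invariant."""


class InsufficientDataError(SpcPipeError):
    """Too few observations to carry out the requested computation."""


class UnsupportedDesignError(SpcPipeError):
    """The study design does not match what the operation requires."""
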
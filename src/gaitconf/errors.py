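"""Exception types raised across the pipeline."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A file does not conform to the expected column schema."""


class ParseError(ValidationError):
    """A file row could not be parsed; the message names the line."""
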
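"""Exception hierarchy for psygset."""


class PsygsetError(Exception):
    """Base class for all psygset errors."""


class ValidationError(PsygsetError, ValueError):
    """A parameter or specification value is inconsistent or out of range."""


class FormatError(PsygsetError, ValueError):
    """An input file does not conform to its expected format."""


class EmptyResultError(PsygsetError, ValueError):
    """An operation produced no usable output (e.g. every disease filtered out)."""
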
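"""Exception types shared across the pipeline."""


class SoilFoodWebError(Exception):
    """Base class for all package errors."""


class ParseError(SoilFoodWebError):
    """A file could not be parsed; message carries the offending location."""


class ValidationError(SoilFoodWebError):
    """A domain-type invariant was violated."""
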
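"""Exception hierarchy for the dyadsync pipeline."""


class DyadsyncError(Exception):
    """Base class for all dyadsync errors."""


class FormatError(DyadsyncError):
    """An input file violates its declared on-disk contract."""


class InsufficientDataError(DyadsyncError):
    """Too few samples/peaks to run the requested operation."""


class ParameterError(DyadsyncError):
    """A configuration value is outside its admissible range."""
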
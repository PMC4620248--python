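"""Exception types shared across the package."""


class DtipairError(ValueError):
    """Base class for all dtipair errors."""


class FormatError(DtipairError):
    """A file could not be parsed in the expected tabular layout."""


class ValidationError(DtipairError):
    """Parsed or constructed data violates a domain invariant."""
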
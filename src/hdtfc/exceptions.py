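"""Exception hierarchy for model configuration, validation, data, and fitting errors."""


class HdtfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HdtfcError, ValueError):
    """A required configuration field is missing or unusable."""


class ValidationError(HdtfcError, ValueError):
    """A supplied value violates a model invariant."""


class DataError(HdtfcError, ValueError):
    """An input file or table is malformed or out of range."""


class FittingError(HdtfcError, RuntimeError):
    """A curve fit failed to converge or was ill-posed."""
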
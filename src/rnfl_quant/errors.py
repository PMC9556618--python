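"""Exception hierarchy for the RNFL quantification pipeline."""


class RNFLQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RNFLQuantError):
    """A configuration object violates one of its invariants."""


class ParameterError(RNFLQuantError):
    """An operation was called with an invalid parameter value."""


class ContractError(RNFLQuantError):
    """Inputs to an operation are mutually inconsistent (e.g. shape mismatch)."""


class DataError(RNFLQuantError):
    """A dataset is empty, malformed, or internally inconsistent."""


class UndefinedCorrelationError(RNFLQuantError):
    """Pearson correlation requested for a zero-variance sequence."""
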
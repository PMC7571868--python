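"""Exception hierarchy for the WFMR pipeline."""


class WfmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WfmrError):
    """A parameter or configuration value is invalid; names the offending field."""


class InputError(WfmrError):
    """An input array/record violates a precondition."""


class FormatError(WfmrError):
    """A file on disk does not follow the expected on-disk format."""


class DegenerateInputError(InputError):
    """Input is structurally valid but carries no usable information
    (e.g. zero-variance RR sequences during synchronization)."""


class EpochSelectionError(WfmrError):
    """Not enough clean 20-s windows could be placed on the record."""

    def __init__(self, message: str, n_placed: int = 0):
        super().__init__(message)
        self.n_placed = n_placed


class EpochInvalidError(WfmrError):
    """An epoch cannot support the requested computation (e.g. < 2 ensembles)."""
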
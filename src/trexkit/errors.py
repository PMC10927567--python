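"""Exception types shared across trexkit modules."""


class TrexkitError(Exception):
    """Base class for all trexkit errors."""


class AlphabetError(TrexkitError, ValueError):
    """A sequence contains characters outside the allowed alphabet."""


class LengthError(TrexkitError, ValueError):
    """A sequence or region is too short/long for the requested operation."""


class ConfigurationError(TrexkitError, ValueError):
    """A parameter combination is invalid or inconsistent with the data."""


class FormatError(TrexkitError, ValueError):
    """An input file does not follow the expected dialect."""


class ImputationError(TrexkitError, ValueError):
    """A column cannot be imputed (too few observed values)."""
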
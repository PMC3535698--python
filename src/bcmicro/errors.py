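"""Exception hierarchy shared across the package."""


class BcmicroError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BcmicroError):
    """A tabular input file is malformed."""


class DuplicateKeyError(ParseError):
    """A (miRNA, gene) or gene key appears more than once."""


class InsufficientDataError(BcmicroError):
    """Too few observations to fit a distribution."""


class DegenerateDataError(BcmicroError):
    """Observations carry no usable variation (e.g. all equal)."""


class FitError(BcmicroError):
    """A maximum-likelihood fit failed to converge."""


class ConfigError(BcmicroError):
    """Inconsistent model/table/configuration combination."""
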
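"""Exception hierarchy for the tfdp package."""


class TFDPError(Exception):
    """Base class for all tfdp errors."""


class InvalidInputError(TFDPError, ValueError):
    """A value passed to an operation violates its preconditions."""


class ConfigurationError(TFDPError, ValueError):
    """A configuration object is internally inconsistent or references unknown names."""


class ParseError(TFDPError, ValueError):
    """A data file could not be parsed into valid melting runs."""


class GridRangeError(TFDPError, ValueError):
    """A target temperature grid exceeds the span of the measured data."""


class DegenerateInputError(TFDPError, ValueError):
    """Input admits no meaningful answer (e.g. clustering identical points)."""


class StratificationError(TFDPError, ValueError):
    """Cross-validation folds cannot be stratified with the given labels."""


class DegenerateSpecWarning(UserWarning):
    """A profile spec produces a featureless (flat) curve."""
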
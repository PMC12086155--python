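"""Exception hierarchy for the leafcolor pipeline."""


class LeafColorError(Exception):
    """Base class for all leafcolor errors."""


class InputError(LeafColorError):
    """Unreadable, malformed, or dimensionally inconsistent input."""


class ConfigError(LeafColorError):
    """Invalid configuration value (unknown mode, bad threshold, ...)."""


class NoGreenPixelsError(LeafColorError):
    """A color statistic was requested on a histogram with no green pixels."""


class InsufficientDataError(LeafColorError):
    """Too few observations for the requested statistic (e.g. n < 2 pairs)."""


class ModelError(LeafColorError):
    """A statistical model could not be fitted (rank deficiency etc.)."""
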
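"""Exception hierarchy shared across the pipeline stages."""


class IsoregError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(IsoregError):
    """A configuration value is invalid; the message names the field."""


class ParseError(IsoregError):
    """A table could not be parsed; the message carries the 1-based row number."""


class FixtureIntegrityError(IsoregError):
    """A packaged fixture is missing, tampered with, or inconsistent."""


class FilterError(IsoregError):
    """FDR estimation or filtering was asked to run on unusable input."""


class QuantificationError(IsoregError):
    """Protein quantification or normalization failed (e.g. too few proteins)."""


class RegulationError(IsoregError):
    """The regulation statistic is undefined for the given inputs."""
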
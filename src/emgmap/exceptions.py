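"""Exception hierarchy shared across the package.

All errors raised by emgmap derive from :class:`EmgMapError` so callers
(including the CLI) can distinguish data/configuration problems from
internal bugs.
"""


class EmgMapError(Exception):
    """Base class for all emgmap errors."""


class InvalidConfigurationError(EmgMapError, ValueError):
    """A configuration value is outside its documented range."""


class InvalidInputError(EmgMapError, ValueError):
    """Input data violates a documented precondition."""


class DegenerateMapError(EmgMapError, ValueError):
    """An operation was asked to act on an all-zero activation map."""


class InvalidDesignError(EmgMapError, ValueError):
    """A statistics table is unbalanced or incomplete."""


class InsufficientDataError(EmgMapError, ValueError):
    """Too few subjects (or levels) for the requested statistic."""
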
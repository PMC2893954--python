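"""Exception hierarchy shared across the package.

Every error raised on bad input derives from :class:`ScreenError` so callers
(and the CLI) can distinguish data problems from programming bugs.
"""


class ScreenError(Exception):
    """Base class for all hrscreen data/configuration errors."""


class AddressError(ScreenError):
    """Malformed or out-of-range well address."""


class FormatError(ScreenError):
    """A table violates the expected file contract (names the offending row)."""


class DegeneratePlateError(ScreenError):
    """A plate whose included wells cannot support z-scoring (sd 0 or n < 2)."""


class MissingDataError(ScreenError):
    """No usable replicate / trigger values where at least one is required."""


class ConfigError(ScreenError):
    """Inconsistent simulation or pipeline configuration."""


class UndefinedRatioError(ScreenError):
    """A normalising denominator (untreated or control mean) is zero."""


class CoordinateError(ScreenError):
    """A coding-variant coordinate falls outside the CDS."""


class SequenceError(ScreenError):
    """A nucleotide or protein string contains unexpected symbols."""


class NomenclatureError(ScreenError):
    """A variant descriptor string could not be parsed."""


class NotAFrameshiftError(ScreenError):
    """The two proteins do not witness a frameshift (no divergence)."""
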
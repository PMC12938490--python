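"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`EmbauditError`,
so callers (and the CLI) can separate audit-framework failures from plain bugs.
"""


class EmbauditError(Exception):
    """Base class for all errors raised by embaudit."""


class TemplateError(EmbauditError, ValueError):
    """A prompt template is malformed (zero or more than one placeholder)."""


class ParameterError(EmbauditError, ValueError):
    """A parameter is outside its admissible range or inconsistent with others."""


class UsageError(EmbauditError, ValueError):
    """An operation was called on inputs that do not satisfy its contract."""


class AlignmentError(EmbauditError, ValueError):
    """Row identifiers of two containers that must be row-aligned do not match."""


class ConfigError(EmbauditError, ValueError):
    """One or more configuration problems; ``errors`` lists all of them."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class CapabilityError(EmbauditError, RuntimeError):
    """A requested optional capability (e.g. a transformer encoder) is unavailable."""


class DegenerateDataError(EmbauditError, ValueError):
    """Data is degenerate for the requested operation (constant target, empty side)."""


class DegenerateDenominatorError(EmbauditError, ArithmeticError):
    """The SD-score denominator is numerically zero (near-perfect reference fit).

    Carries the raw summed distances so the caller can inspect them instead of
    receiving a silent infinity.
    """

    def __init__(self, message, numerator, denominator):
        self.numerator = float(numerator)
        self.denominator = float(denominator)
        super().__init__(
            f"{message} (numerator={numerator!r}, denominator={denominator!r})"
        )
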
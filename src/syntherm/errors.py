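"""Exception hierarchy.

All package-specific failures derive from :class:`SynthermError` so callers
(and the CLI) can distinguish configuration mistakes (exit code 2) from
thermodynamic domain violations (exit code 3).
"""


class SynthermError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(SynthermError, ValueError):
    """A configuration file or parameter set is malformed or inconsistent."""


class UsageError(SynthermError, ValueError):
    """An operation was applied to an object it is not defined for."""


class UnknownSpeciesError(SynthermError, KeyError):
    """A species name could not be resolved in a table or activity set."""

    def __init__(self, name: str, context: str = "Gibbs table"):
        super().__init__(f"species {name!r} not found in {context}")
        self.species = name


class UnbalancedReactionError(SynthermError, ValueError):
    """A reaction fails element or charge balance."""


class ActivityDomainError(SynthermError, ValueError):
    """An activity or partial pressure is outside the domain of ln()."""


class ParseError(SynthermError, ValueError):
    """A delimited-text input could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InsufficientDataError(SynthermError, ValueError):
    """Too few uncensored observations for the requested estimate."""


class UndefinedRatioError(SynthermError, ValueError):
    """A stoichiometric ratio is undefined (zero substrate turnover)."""


class UndefinedPartitionError(SynthermError, ValueError):
    """Energy shares are undefined because the total reaction is not exergonic."""
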
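"""Exception hierarchy.

Every failure mode the toolkit can hit maps to one of these classes so the
CLI can translate them into distinct exit codes and user-facing messages.
"""


class NitrocalcError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ParameterError(NitrocalcError, ValueError):
    """A numeric argument is outside its physical domain (negative nitrite,
    conversion fraction above 1, zero molecular weight, ...)."""

    exit_code = 2


class FormulationError(NitrocalcError, ValueError):
    """A formulation violates its invariants (fractions not summing to
    100 % w/w, duplicate ingredient names, non-positive tablet weight)."""

    exit_code = 3


class SchemaError(NitrocalcError, ValueError):
    """A data file does not match the expected schema; the message cites
    the offending row/field."""

    exit_code = 4


class NitriteLookupError(NitrocalcError, KeyError):
    """An excipient key is not in the nitrite database; the message lists
    the nearest matching keys."""

    exit_code = 5


class ConversionLookupError(NitrocalcError, KeyError):
    """A (amine type, amine form, process, amine class) combination has no
    registered conversion fraction."""

    exit_code = 5


class NoCrossingError(NitrocalcError, ValueError):
    """A threshold inversion was requested for a scenario whose response
    slope is zero (no nitrite load), so no finite crossing exists."""

    exit_code = 6
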
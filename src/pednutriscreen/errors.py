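"""Exception hierarchy shared across the package."""


class PedNutriScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PedNutriScreenError, ValueError):
    """Malformed input file: missing columns, unparsable numbers, unsorted axis."""


class ValidityError(PedNutriScreenError, ValueError):
    """Structurally parsable input that violates a domain invariant (e.g. S <= 0)."""


class DomainError(PedNutriScreenError, ValueError):
    """A numeric argument outside the mathematical domain of an operation."""


class OutOfRangeError(PedNutriScreenError, ValueError):
    """Axis query outside a growth-reference table; no extrapolation is done."""


class RegistryLookupError(PedNutriScreenError, KeyError):
    """Diagnosis code absent from the diagnosis registry."""


class ConfigurationError(PedNutriScreenError, ValueError):
    """Missing reference table, malformed thresholds block, or invalid simulation config."""


class InputError(PedNutriScreenError, ValueError):
    """Invalid data passed to a diagnostic computation (length mismatch, single class, ...)."""


class ComputationError(PedNutriScreenError, ArithmeticError):
    """A statistic cannot be computed on this input (e.g. zero expected cell)."""


class ReconstructionError(PedNutriScreenError, ValueError):
    """No (or no unique) joint distribution is consistent with the printed constraints."""
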
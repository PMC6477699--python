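"""Exception hierarchy shared by all gagabind modules."""


class GagabindError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(GagabindError, ValueError):
    """A sequence or pattern contains characters outside the accepted alphabet."""


class ContractError(GagabindError, ValueError):
    """An operation was called with arguments violating its contract."""


class InfeasibleDesignError(GagabindError, ValueError):
    """No probe derivative satisfies the titration constraints within budget."""


class InsufficientReplicationError(GagabindError, ValueError):
    """A binding statistic requires more replicates than were supplied."""


class NormalizationError(GagabindError, ValueError):
    """Background/reference normalization is undefined for these signals."""


class UndefinedCorrelationError(GagabindError, ValueError):
    """Correlation is undefined because one axis is constant."""


class FormatError(GagabindError, ValueError):
    """A text input file violates its format (bedGraph, alignment, ...)."""


class DomainError(GagabindError, ValueError):
    """A parameter lies outside the mathematical domain of the operation."""
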
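"""Exception hierarchy shared across the package."""


class CranolexError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CranolexError, ValueError):
    """A parameter violates its documented domain."""


class UnrecoverableSpecimenError(CranolexError):
    """A specimen cannot be imputed (e.g. missing midline landmark)."""


class DegenerateInputError(CranolexError):
    """Input is rank-deficient or constant where variation is required."""


class UndefinedDistanceError(CranolexError):
    """A distance is undefined (e.g. doculects share no concepts)."""


class NoCandidatesError(CranolexError):
    """No candidate doculect matches a population's selection heuristics."""


class RoutingError(CranolexError):
    """No waypoint route is defined for a continent pair."""


class FormatError(CranolexError, ValueError):
    """A file does not conform to its documented dialect."""
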
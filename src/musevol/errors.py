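"""Exception hierarchy for musevol."""


class MusevolError(Exception):
    """Base class for all musevol errors."""


class InvalidParameterError(MusevolError, ValueError):
    """A distribution or selection parameter violates its domain."""


class NotBetaRepresentableError(MusevolError, ValueError):
    """A (mean, sd) pair lies outside the beta-representable region
    sigma^2 < mu*(1-mu)."""


class IllDefinedSelectionError(MusevolError, ValueError):
    """Selection coefficients make the reweighted density non-integrable."""


class NumericalError(MusevolError, ArithmeticError):
    """Quadrature or optimisation failed to converge."""


class FittingError(MusevolError, ValueError):
    """Distribution or dynamical-model fitting cannot proceed."""


class UndefinedFrequencyError(MusevolError, ValueError):
    """A per-piece frequency is requested from too short a sequence."""


class FormatError(MusevolError, ValueError):
    """A corpus file does not parse under the named format."""


class EmptyPieceError(FormatError):
    """A corpus file parsed but contains no note events."""
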
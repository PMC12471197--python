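"""Exception hierarchy for predfr.

All errors raised by the library derive from :class:`PredfrError` so callers
can catch one base class; each subclass also derives from the matching
builtin (``ValueError``) so generic handling keeps working.
"""


class PredfrError(Exception):
    """Base class for all predfr errors."""


class InvalidInputError(PredfrError, ValueError):
    """An argument violates a precondition (negative density, non-finite b, ...)."""


class UnderdeterminedError(PredfrError, ValueError):
    """Too few distinct prey densities to identify the requested model."""


class DegenerateDataError(PredfrError, ValueError):
    """Data carry no usable signal (e.g. all consumption ratios identically zero)."""


class NoPredationError(PredfrError, ValueError):
    """Every trial recorded zero consumption; the disc equation cannot be fitted."""


class UndefinedRateError(PredfrError, ValueError):
    """A detection rate over zero assayed individuals (distinct from a true 0%)."""


class InvalidConfigError(PredfrError, ValueError):
    """A simulation configuration violates its invariants."""


class ValidationError(PredfrError, ValueError):
    """An input file failed row-level validation; message names file and row."""
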
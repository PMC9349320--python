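"""Exception hierarchy for mmclonal.

All package errors derive from :class:`MMClonalError` so callers can catch
one base class; subclasses discriminate format problems (bad input files)
from domain problems (arguments outside the model's preconditions).
"""


class MMClonalError(Exception):
    """Base class for all mmclonal errors."""


class FormatError(MMClonalError):
    """An input file does not conform to the expected dialect."""


class ReconciliationError(MMClonalError):
    """Mutation table and sample sheet disagree about sample identity."""


class ConfigurationError(MMClonalError):
    """A configuration value or combination is invalid."""


class DomainError(MMClonalError, ValueError):
    """An argument violates a mathematical precondition (e.g. purity <= 0)."""


class MissingCopyNumberError(MMClonalError):
    """No copy-number segment covers a mutated locus in a sample."""


class IntegrityError(MMClonalError):
    """An internal structure (e.g. a clone tree) is inconsistent."""


class GenerationError(MMClonalError):
    """A simulation configuration is infeasible."""
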
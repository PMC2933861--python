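"""Exception hierarchy.

Every error raised by this package derives from :class:`DinuqcError` so callers
(and the CLI) can catch one base class. Subclasses distinguish the failure modes
the library contracts promise to report separately.
"""


class DinuqcError(Exception):
    """Base class for all dinuqc errors."""


class InvalidSequenceError(DinuqcError, ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class DegenerateSequenceError(DinuqcError, ValueError):
    """Too little informative sequence to compute the requested quantity."""


class ConfigurationError(DinuqcError, ValueError):
    """Incompatible options or operands (e.g. mixed symmetrization flags)."""


class InsufficientDataError(DinuqcError, ValueError):
    """Not enough data points survive filtering (e.g. < 3 shared windows)."""


class LayoutError(DinuqcError, ValueError):
    """An assembly layout is malformed or inconsistent with its sequences."""


class SpecError(DinuqcError, ValueError):
    """A synthetic-genome specification is infeasible or self-contradictory."""


class FastaError(DinuqcError, ValueError):
    """Base class for FASTA reading problems."""


class EmptyInputError(FastaError):
    """An input file contains no records."""


class DuplicateRecordError(FastaError):
    """Two FASTA records share an identifier."""


class TruncatedFileError(FastaError):
    """A (gzip-compressed) input ends prematurely."""
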
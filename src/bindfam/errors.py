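"""Exception hierarchy.

All package-specific failures derive from :class:`BindfamError` so callers
can catch one base type; most also derive from ``ValueError`` because they
signal invalid inputs rather than internal faults.
"""


class BindfamError(Exception):
    """Base class for all bindfam errors."""


class AlignmentFormatError(BindfamError, ValueError):
    """Alignment file is malformed (e.g. unequal aligned lengths)."""


class InsufficientMembersError(BindfamError, ValueError):
    """A family has fewer members (or annotated members) than required."""


class PositionParseError(BindfamError, ValueError):
    """A residue-position table contains non-positive or non-integer values."""


class ConsistencyError(BindfamError, ValueError):
    """Annotation/prediction positions conflict with the sequence length."""


class UndefinedSimilarityError(BindfamError, ValueError):
    """Pairwise similarity requested for an empty binding-residue set."""


class InsufficientDataError(BindfamError, ValueError):
    """Fewer than two units available for a mean/standard-error aggregate."""


class ConfigurationError(BindfamError, ValueError):
    """A run configuration is incomplete or infeasible."""
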
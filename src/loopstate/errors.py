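"""Exception hierarchy.

All errors raised by this package derive from :class:`LoopstateError` so
callers can catch one type at a pipeline boundary.  Data problems (bad
files, missing atoms) and usage problems (bad parameters, bad config) are
kept distinct for CLI exit codes.
"""


class LoopstateError(Exception):
    """Base class for all package errors."""


# --- usage / configuration ------------------------------------------------

class ParameterError(LoopstateError):
    """A function argument is out of its documented domain."""


class SchemaError(LoopstateError):
    """A config, table or model does not match the expected schema."""


class InsufficientDataError(LoopstateError):
    """Not enough observations to fit or summarize."""


# --- data -----------------------------------------------------------------

class StructureParseError(LoopstateError):
    """A structure/trajectory file could not be parsed."""


class EmptyStructureError(LoopstateError):
    """A structure file contained no atoms."""


class TopologyMismatchError(LoopstateError):
    """Topology atom count differs from per-frame atom count."""


class MissingAtomError(LoopstateError):
    """A named residue/atom could not be resolved in a frame."""


class AmbiguousAtomError(LoopstateError):
    """An atom selection matched more than one atom."""


class EmptySelectionError(LoopstateError):
    """A residue-range selection matched no atoms."""


class MissingHydrogenError(LoopstateError):
    """Hydrogen-aware detection requested on a structure without hydrogens."""


# --- geometry / series ----------------------------------------------------

class DegenerateGeometryError(LoopstateError):
    """Too few or collinear points for the requested geometric operation."""


class InfeasibleGeometryError(LoopstateError):
    """Requested construction has no solution (e.g. partners too far)."""


class NotApplicableError(LoopstateError):
    """Metric undefined for this frame (e.g. ICL2 not helical)."""


class EmptySeriesError(LoopstateError):
    """A per-frame or per-replicate series is empty."""
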
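"""Exception hierarchy for kinasedyn.

Every error raised by the package derives from :class:`KinasedynError`
so callers can catch the whole family with a single clause.
"""


class KinasedynError(Exception):
    """Base class for all kinasedyn errors."""


class FormatError(KinasedynError):
    """A file could not be parsed under the named standard."""


class EmptyInputError(KinasedynError):
    """An input file or model contained no usable records."""


class TopologyError(KinasedynError):
    """Atom counts or topologies are inconsistent."""


class ConfigurationError(KinasedynError):
    """Required configuration (e.g. a frame time map) is missing or invalid."""


class SelectionError(KinasedynError):
    """A segment selection is malformed or falls outside the topology."""


class EmptySelectionError(SelectionError):
    """A selection resolved to zero atoms."""


class DegenerateGeometryError(KinasedynError):
    """A geometric construction is undefined (e.g. a zero-length ray)."""


class UnderdeterminedFitError(KinasedynError):
    """Too few (or collinear) atoms to determine a rigid-body fit."""


class EmptySeriesError(KinasedynError):
    """A metric series has no retained values."""


class AtomSetError(KinasedynError):
    """A residue lacks the atoms required by an interaction detector."""


class AggregationError(KinasedynError):
    """Replica series being aggregated do not describe the same quantity."""


class IncompatibleEnsemblesError(KinasedynError):
    """Trajectories cannot be pooled (selection atom counts differ)."""
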
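"""Exception and warning types shared across the package."""


class RefnetError(Exception):
    """Base class for all package errors."""


class SchemaError(RefnetError):
    """A feature or record is missing a required property or holds an
    out-of-vocabulary value; the message names the offending id."""


class CoordinateSystemError(RefnetError):
    """Input geodata is not declared as planar with kilometre units.

    Geographic (lon/lat) coordinates are rejected rather than silently
    projected: all distances here are ground distances on a projected plane.
    """


class ConsistencyError(RefnetError):
    """A record violates a structural implication, e.g. a call marked as
    having used the dispatched transport without having complied."""


class DateRangeError(RefnetError):
    """A call date falls outside the operational window of the call centre."""


class UndefinedSpeedError(RefnetError, KeyError):
    """The speed table defines no entry for this (mode, road type) pair."""


class UnreachableError(RefnetError):
    """No path exists between origin and destination under the mode policy."""


class UnassignedVillageError(RefnetError):
    """The village has no catchment assignment."""


class GenerationError(RefnetError):
    """The synthetic-scenario configuration is infeasible."""


class DegenerateGeometryError(RefnetError):
    """A geometry required to have positive measure is empty or zero-area."""


class IsolationWarning(UserWarning):
    """A village lies farther than the maximum connector distance from the
    transport network and was left unconnected."""


class PartialCoverageWarning(UserWarning):
    """Excluding a route left one or more villages with no active route."""


class UnassignedWarning(UserWarning):
    """A village could reach no active route pickup point."""
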
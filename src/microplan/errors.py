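"""Exception hierarchy for the microplan pipeline.

All pipeline errors derive from :class:`MicroplanError` so callers can
catch the package's failures with a single except clause while still
distinguishing configuration mistakes from data problems.
"""


class MicroplanError(Exception):
    """Base class for all errors raised by this package."""


class InvalidConfigError(MicroplanError, ValueError):
    """A configuration value violates its stated constraints."""


class ValidationError(MicroplanError, ValueError):
    """Input data fails schema or consistency validation."""


class FormatError(MicroplanError, ValueError):
    """A file is syntactically readable but internally inconsistent."""


class GeometryError(MicroplanError, ValueError):
    """A polygon or other geometry is invalid for the requested operation."""


class UnreachableFacilityError(MicroplanError):
    """A facility lies farther than ``max_snap_m`` from every traversable edge.

    Batch operations catch this per facility and report it in the skipped
    list instead of aborting the whole run.
    """

    def __init__(self, facility_id, snap_distance_m=None, max_snap_m=None):
        self.facility_id = facility_id
        self.snap_distance_m = snap_distance_m
        self.max_snap_m = max_snap_m
        msg = f"facility {facility_id!r} is not within snapping range of any traversable edge"
        if snap_distance_m is not None and max_snap_m is not None:
            msg += f" (nearest edge {snap_distance_m:.1f} m away, max_snap_m={max_snap_m:.1f})"
        super().__init__(msg)


class ConsistencyError(MicroplanError, ValueError):
    """Two inputs that must describe the same entities do not match."""
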
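"""Exception hierarchy."""


class TargetECError(Exception):
    """Base class for all targetec errors."""


class MalformedIntervalError(TargetECError):
    """An interval with start >= end, or a negative coordinate."""


class UnknownContigError(TargetECError):
    """A contig name that is not present in the governing ContigSpace."""


class OutOfBoundsError(TargetECError):
    """An interval extending beyond its contig length."""


class MalformedTrackError(TargetECError):
    """A score/coverage track with overlapping runs or out-of-range values."""


class EmptyInputError(TargetECError):
    """A statistic requested over an empty region or read set."""


class NoValidPlacementError(TargetECError):
    """A deletion length longer than every contig: no placement exists."""


class VcfParseError(TargetECError):
    """A VCF file or record that could not be parsed."""


class FixtureError(TargetECError):
    """Infeasible synthetic-fixture specification (e.g. genes do not fit)."""


class InternalConsistencyError(TargetECError):
    """A derived structure violating its own invariant (partition, sums)."""
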
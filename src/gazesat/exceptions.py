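"""Exception types shared across the package."""


class GazeSatError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GazeSatError):
    """An input table is missing a required column."""


class EmptyInputError(GazeSatError):
    """An input file or collection contained no usable rows."""


class InsufficientDataError(GazeSatError):
    """Too few samples for the requested statistic."""


class GeometryMismatchError(GazeSatError):
    """Two maps do not share the same stimulus geometry / downscale."""


class UndefinedAUCError(GazeSatError):
    """AUC is undefined because the benchmark labels are one-sided."""


class LeaveNOutError(GazeSatError):
    """A requested sample size violates the leave-n-out constraint n <= N/2."""


class UndefinedChangeError(GazeSatError):
    """Percentage change from a zero baseline is undefined."""


class MissingSampleSizeError(GazeSatError):
    """A requested sample size is not present in the curve."""


class UnknownProfileError(GazeSatError):
    """An unrecognised synthetic-data profile name."""
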
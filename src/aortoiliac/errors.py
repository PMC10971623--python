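"""Exception hierarchy for the aortoiliac morphometry toolkit."""


class AortoiliacError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AortoiliacError):
    """An input file violates its declared dialect (missing columns, bad XML, ...)."""


class StructureError(AortoiliacError):
    """Branch connectivity does not form a valid rooted vessel tree."""


class AmbiguityError(StructureError):
    """Automatic anatomical labeling cannot decide; explicit labels required."""


class ParameterError(AortoiliacError, ValueError):
    """A numeric or categorical parameter is outside its admissible range."""


class GeometryError(AortoiliacError):
    """A geometric construction is undefined for the given points."""


class MissingDataError(AortoiliacError):
    """Required per-point data (e.g. radii) are absent."""


class UndefinedMetricError(AortoiliacError):
    """A metric is mathematically undefined for this input (e.g. closed curve TI)."""
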
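"""Exception hierarchy."""


class ScalemapError(Exception):
    """Base class for all package errors."""


class AdjacencyParseError(ScalemapError):
    """A neighbour file could not be parsed; message names the line."""


class AsymmetricAdjacencyError(ScalemapError):
    """Directed input where an undirected graph is required; lists offending pairs."""


class NestingConflictError(ScalemapError):
    """A fine unit is assigned to more than one coarse unit."""


class MissingDataError(ScalemapError):
    """A unit present in the geography has no value in the data."""


class DegenerateCovariateError(ScalemapError):
    """Covariate has zero variance; standardization is undefined."""


class IslandError(ScalemapError):
    """An ICAR conditional was requested for a unit with no neighbours."""


class DimensionError(ScalemapError):
    """A vector's length does not match the geography at its level."""


class InitializationError(ScalemapError):
    """The sampler's initial state has non-finite posterior density."""


class SamplingError(ScalemapError):
    """A non-finite value appeared during sampling."""
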
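"""Exception hierarchy shared by all analysis stages."""


class HalomodeError(Exception):
    """Base class for every error raised by this package."""


class PDBFormatError(HalomodeError, ValueError):
    """A structure file violates the multi-model PDB subset we read."""


class SelectionError(HalomodeError, ValueError):
    """An atom selection resolved to nothing (or referenced missing atoms)."""


class GeometryError(HalomodeError, ValueError):
    """Degenerate geometry: too few points, collinear sets, zero variance."""


class InsufficientDataError(HalomodeError, ValueError):
    """Fewer observations than the statistic requires."""


class ConfigError(HalomodeError, ValueError):
    """A run or criteria configuration is invalid."""


class SpecError(HalomodeError, ValueError):
    """A synthetic-trajectory specification is invalid or infeasible."""


class DegenerateInputError(HalomodeError, ValueError):
    """Input with no usable structure (e.g. an all-zero distance matrix)."""
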
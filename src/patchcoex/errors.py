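"""Exception hierarchy for patchcoex."""


class PatchcoexError(Exception):
    """Base class for all patchcoex errors."""


class InvalidOutlineError(PatchcoexError):
    """The polygon outline violates its invariants (too few vertices,
    self-intersection, zero or negative area)."""


class UnsupportedTopologyError(PatchcoexError):
    """Outline input contains topology we do not model (holes, multi-part)."""


class OutlineParseError(PatchcoexError):
    """Malformed GeoJSON; carries the offending feature index where known."""

    def __init__(self, message: str, feature_index: int | None = None):
        super().__init__(message)
        self.feature_index = feature_index


class ResolutionTooCoarseError(PatchcoexError):
    """Rasterization produced no interior cells at the requested resolution."""

    def __init__(self, message: str, min_feasible: int | None = None):
        super().__init__(message)
        self.min_feasible = min_feasible


class GenerationFailureError(PatchcoexError):
    """Synthetic island generator failed to produce a simple polygon."""


class DegenerateSystemError(PatchcoexError):
    """All diffusion coefficients and growth rates are zero: no timescale."""


class NumericalInstabilityError(PatchcoexError):
    """The explicit scheme produced a non-finite or strongly negative value."""

    def __init__(self, message: str, step: int = -1, cell: int = -1, species: int = -1):
        super().__init__(message)
        self.step = step
        self.cell = cell
        self.species = species


class KernelTooWideError(PatchcoexError):
    """Dispersal-kernel width exceeds half the domain extent."""


class WrongDimensionalityError(PatchcoexError):
    """Operation requires a 2-D raster domain (or a 1-D interval)."""


class UndefinedCorrelationError(PatchcoexError):
    """Correlation requested for a constant (zero-variance) input."""
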
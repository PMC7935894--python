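"""Exception types shared across the package."""


class PaleonicheError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PaleonicheError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class InfeasibleSamplingError(PaleonicheError, ValueError):
    """A sampling request cannot be satisfied (e.g. too few eligible cells)."""


class DegenerateGeometryError(PaleonicheError, ValueError):
    """Point configuration does not support the requested geometric fit."""


class ExtractionError(PaleonicheError, ValueError):
    """Points fall off-grid or on masked cells during value extraction."""


class SpaceMismatchError(PaleonicheError, ValueError):
    """Environmental matrices live in incompatible spaces."""


class UndefinedOverlapError(PaleonicheError, ValueError):
    """Jaccard overlap is undefined (no cloud point inside either ellipsoid)."""


class PipelineStageError(PaleonicheError, RuntimeError):
    """A pipeline stage failed; carries the stage name for replay."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
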
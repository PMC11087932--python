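"""Exception hierarchy shared across the pipeline stages."""


class GlioCNVError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GlioCNVError, ValueError):
    """A user-supplied parameter is out of its allowed range."""


class InvalidBuildError(GlioCNVError, ValueError):
    """A genome build definition violates its invariants."""


class MarkerLookupError(GlioCNVError, KeyError):
    """A requested marker is unknown or not defined for the build."""


class GridConsistencyError(GlioCNVError, ValueError):
    """Two objects that must share a bin grid do not."""


class InputFormatError(GlioCNVError, ValueError):
    """A file does not conform to the expected on-disk format."""


class InsufficientDataError(GlioCNVError, ValueError):
    """Too few usable bins/points to carry out the computation."""


class BaselineError(GlioCNVError, ValueError):
    """The deletion baseline is unusable (e.g. non-negative slope)."""


class PipelineStageError(GlioCNVError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
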
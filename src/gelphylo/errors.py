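"""Exception hierarchy for the gelphylo pipeline.

Every stage raises a subclass of :class:`GelPhyloError`, so callers (and the
pipeline driver) can catch one type and still report the offending stage.
"""


class GelPhyloError(Exception):
    """Base class for all gelphylo errors."""


class FormatError(GelPhyloError):
    """An input file is malformed or of an unsupported format."""


class BoundsError(GelPhyloError):
    """A requested region or index lies outside the image."""


class DetectionError(GelPhyloError):
    """Automatic detection cannot proceed (e.g. a signal-free profile)."""


class ConflictError(GelPhyloError):
    """A manual edit conflicts with existing objects (overlapping lanes)."""


class NotFoundError(GelPhyloError):
    """A referenced object (lane, band, file, standard) does not exist."""


class PairingError(GelPhyloError):
    """Marker band count does not match the standard's weight count."""


class SingularFitError(GelPhyloError):
    """The calibration fit is degenerate (all migration distances equal)."""


class MatrixError(GelPhyloError):
    """A distance/similarity matrix violates its contract."""


class SceneError(GelPhyloError):
    """A synthetic-gel scene is unrenderable (band outside the image)."""


class LabelError(GelPhyloError):
    """A relabeling would produce duplicate leaf names."""


class ParseError(GelPhyloError):
    """A tree or matrix text file cannot be parsed."""


class PipelineError(GelPhyloError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
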
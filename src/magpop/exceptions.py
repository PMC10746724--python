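"""Exception hierarchy shared by all magpop modules."""


class MagpopError(Exception):
    """Base class for all errors raised by magpop."""


class FormatError(MagpopError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(MagpopError):
    """In-memory data violates a documented invariant."""


class NoOverlapError(MagpopError):
    """A pair of samples shares no usable positions; the pair is missing, not zero."""


class MatrixIncompleteError(MagpopError):
    """A distance matrix has missing pairs and cannot be used downstream.

    Carries ``pairs``, the list of (sample_x, sample_y) tuples that could not
    be computed.
    """

    def __init__(self, message: str, pairs=None):
        super().__init__(message)
        self.pairs = list(pairs or [])


class DegenerateFitError(MagpopError):
    """A regression cannot be fitted (zero predictor variance or n too small)."""


class PipelineStageError(MagpopError):
    """A pipeline stage failed; carries the stage name and the offending MAG."""

    def __init__(self, stage: str, mag_id: str, message: str):
        super().__init__(f"stage {stage!r} failed for MAG {mag_id!r}: {message}")
        self.stage = stage
        self.mag_id = mag_id
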
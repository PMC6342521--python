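"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A run or object was configured inconsistently (missing constants, bad grid, unknown law)."""


class CalibrationError(RuntimeError):
    """Depth calibration of a z-stack failed (e.g. an anchor slice has no usable foreground)."""


class EstimationError(RuntimeError):
    """An automatic estimate (e.g. singlet volume) could not be formed; a manual override is advised."""


class PlacementError(RuntimeError):
    """Aggregates could not be placed in the synthetic imaging volume without overlap."""


class SegmentationError(RuntimeError):
    """A stage of the stack-segmentation chain failed; the message names the stage."""
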
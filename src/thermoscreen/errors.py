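"""Exception hierarchy shared across the pipeline stages."""


class ThermoscreenError(Exception):
    """Base class for all pipeline errors."""


class ProtocolError(ThermoscreenError, ValueError):
    """Invalid scan protocol or tissue parameters."""


class GeometryError(ThermoscreenError, ValueError):
    """ROI outside the frame, overlapping regions, or shape mismatch."""


class QualityError(ThermoscreenError, ValueError):
    """Signal too short/degenerate for a reliable fit."""


class ConfigurationError(ThermoscreenError, ValueError):
    """Invalid cohort/pipeline configuration."""


class TrainingError(ThermoscreenError, RuntimeError):
    """Classifier training failed (single class, non-convergence, ...)."""
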
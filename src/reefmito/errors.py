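"""Exception hierarchy shared across the pipeline."""


class ReefmitoError(Exception):
    """Base class for all package errors."""


class ValidationError(ReefmitoError, ValueError):
    """Input fails a structural or range invariant."""


class AlignmentShapeError(ValidationError):
    """Sequences in an alignment do not share a common length."""


class CrossReferenceError(ValidationError):
    """Alignment ids and metadata ids do not match up."""


class InsufficientDataError(ReefmitoError, ValueError):
    """Too few observations for the requested summary."""


class StratumError(ReefmitoError, ValueError):
    """Hierarchical design is degenerate (missing or empty strata)."""


class ParameterError(ReefmitoError, ValueError):
    """A tuning parameter is outside its admissible range."""
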
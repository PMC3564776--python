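"""Exception and warning types shared across the pipeline.

Every stage raises a subclass of :class:`ThermocompError` so callers can
distinguish pipeline failures from programming errors.
"""


class ThermocompError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(ThermocompError):
    """Input violates a format or alphabet contract."""


class EmptyInputError(ThermocompError):
    """An input that must be non-empty was empty."""


class ParameterError(ThermocompError):
    """A parameter is outside its admissible range."""


class ConfigurationError(ThermocompError):
    """Inconsistent run configuration (e.g. colliding measure names)."""


class UndefinedCompositionError(ThermocompError):
    """Sequence has no unambiguous residues; composition is undefined."""


class FrameError(ThermocompError):
    """Coding sequence length is not a multiple of three."""


class DegenerateInputError(ThermocompError):
    """Zero-variance or otherwise degenerate input to a correlation."""


class InsufficientOverlapError(ThermocompError):
    """Fewer than the minimum number of shared keys between two tables."""


class UndefinedRocError(ThermocompError):
    """ROC analysis requested on single-class data."""


class NoTransitionError(ThermocompError):
    """Melt curve shows no rising unfolding transition."""


class UntrimmableAlignmentError(ThermocompError):
    """Alignment has no column that is gap-free in every row."""


class UnreliableFitWarning(UserWarning):
    """Fitted parameters fall outside the trustworthy region."""
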
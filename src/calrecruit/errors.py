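"""Exception hierarchy for calrecruit."""


class CalrecruitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CalrecruitError, ValueError):
    """Invalid simulation or model configuration."""


class ParameterError(CalrecruitError, ValueError):
    """Invalid operation parameter (window width, duration, ...)."""


class LayoutError(CalrecruitError, ValueError):
    """Requested soma layout does not fit the movie canvas."""


class EmptyInputError(CalrecruitError, ValueError):
    """Operation received an empty movie/trace/table."""


class RoiBoundsError(CalrecruitError, ValueError):
    """ROI pixels fall outside the movie frame."""


class StageError(CalrecruitError, ValueError):
    """Trace is at the wrong processing stage for this operation."""


class DegenerateBaselineError(CalrecruitError, ValueError):
    """Estimated baseline F0 is non-positive somewhere."""


class LengthError(CalrecruitError, ValueError):
    """Trace too short for the requested feature computation."""


class TrainingError(CalrecruitError, ValueError):
    """Classifier training set is unusable (e.g. single class)."""


class SchemaError(CalrecruitError, ValueError):
    """Tabular input does not match the expected schema/dimensionality."""


class ReferenceError_(CalrecruitError, KeyError):
    """A correction or comparison references an unknown id/cell."""


class WindowError(CalrecruitError, ValueError):
    """Analysis windows overlap or fall outside the recording."""


class DesignError(CalrecruitError, ValueError):
    """Statistical design is degenerate (empty cell, single level)."""


class DegenerateTableError(CalrecruitError, ValueError):
    """Contingency table has a zero marginal."""
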
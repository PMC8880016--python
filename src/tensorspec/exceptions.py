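"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3. ``StageError`` wraps a failure with the pipeline stage
name attached.
"""


class TensorSpecError(Exception):
    """Base class for all tensorspec errors."""


class ConfigError(TensorSpecError):
    """Invalid configuration or parameter value."""


class DataError(TensorSpecError):
    """Invalid or malformed input data."""


class FormatError(DataError):
    """Structurally broken file (ragged rows, unknown layout)."""


class ParseError(DataError):
    """Non-numeric value where a number was expected."""


class LabelingError(DataError):
    """Class labels missing or not resolvable for every sample."""


class BandError(DataError):
    """Requested wavenumber band does not intersect the grid."""


class SelectionError(DataError):
    """Characteristic-wavenumber selection produced an empty set."""


class DegenerateInputError(DataError):
    """Input too small or otherwise degenerate for the operation."""


class BalanceError(DataError):
    """Classes are not balanced where a balanced tensor is required."""


class TrainingError(DataError):
    """Classifier training impossible (e.g. a single class)."""


class StratificationError(DataError):
    """A class is too small for the requested number of CV folds."""


class StageError(TensorSpecError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
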
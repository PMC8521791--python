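"""Exception hierarchy for worktrack.

Every error raised by the package derives from :class:`WorktrackError` so
callers can catch the whole family with one clause.
"""


class WorktrackError(Exception):
    """Base class for all worktrack errors."""


# --- sensor stream I/O ------------------------------------------------------

class MissingChannelError(WorktrackError):
    """A required channel column is absent from a CSV file."""


class NonMonotoneTimestampsError(WorktrackError):
    """Timestamps are not strictly increasing."""


class MalformedRowError(WorktrackError):
    """A cell that must be numeric is missing or non-numeric."""


class EmptyStreamError(WorktrackError):
    """The stream is too short for the requested operation."""


class UnwritablePathError(WorktrackError):
    """The output path cannot be written."""


# --- synthetic data ---------------------------------------------------------

class InvalidDurationError(WorktrackError):
    """Episode duration must be positive."""


class InvalidRateError(WorktrackError):
    """Sampling rate must be positive."""


class InvalidCountError(WorktrackError):
    """Subject count must be at least 1."""


# --- features ---------------------------------------------------------------

class UnlabeledStreamError(WorktrackError):
    """A stream without labels cannot enter the supervised pipeline."""


class EmptyClassError(WorktrackError):
    """No samples of the requested activity class are present."""


class NonFiniteMatrixError(WorktrackError):
    """A matrix contains NaN or infinite entries."""


# --- models -----------------------------------------------------------------

class UnknownVariantError(WorktrackError):
    """Model variant is not one of CNN1/CNN2/CNN3/SVM/RF."""


class BadFeatureCountError(WorktrackError):
    """Feature count must be 27 or 18."""


class EmptyDatasetError(WorktrackError):
    """Training requires a non-empty dataset."""


class FeatureModeMismatchError(WorktrackError):
    """Dataset/sample feature mode differs from the model's."""


class ShapeMismatchError(WorktrackError):
    """Sample shape does not match the model input shape."""


# --- evaluation -------------------------------------------------------------

class LengthMismatchError(WorktrackError):
    """Truth and prediction sequences differ in length."""


class UnknownLabelError(WorktrackError):
    """A label outside the canonical 7-class set was encountered."""


class EmptyMatrixError(WorktrackError):
    """Confusion matrix contains no counts."""


class TooFewSamplesError(WorktrackError):
    """A class has fewer samples than the number of folds."""


class SingleSubjectError(WorktrackError):
    """Leave-one-subject-out needs at least two subjects."""


class MissingWorkingClassError(WorktrackError):
    """A working class (Re/Ty/Wr) is absent from the report."""


# --- realtime ---------------------------------------------------------------

class EmptyTimelineError(WorktrackError):
    """The prediction timeline holds no entries."""
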
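"""Exception hierarchy shared across the package."""


class CseRecallError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(CseRecallError):
    """Word-list design violates an invariant (length, ordering, regions)."""


class InvalidFrequencyError(CseRecallError):
    """Relative word frequency outside (0, 1]."""


class ItemIndexError(CseRecallError, IndexError):
    """Item order index outside 1..L."""


class FormatError(CseRecallError):
    """Malformed input file; message names the offending row/column."""


class DegenerateDataError(CseRecallError):
    """Response data carry no information (all identical, all extreme)."""


class ConvergenceError(CseRecallError):
    """Iterative estimation failed to converge; carries diagnostics."""

    def __init__(self, message, *, iterations=None, max_change=None):
        super().__init__(message)
        self.iterations = iterations
        self.max_change = max_change


class DegeneratePCAError(CseRecallError):
    """PCA input has no usable variance."""


class DegenerateRegressionError(CseRecallError):
    """Design matrix rank-deficient after centering."""


class ParameterError(CseRecallError, ValueError):
    """Configuration or argument outside its documented range."""


class UndefinedScoreError(CseRecallError):
    """A score requested over an empty set of observations."""
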
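"""Exception and warning types shared across the package."""


class NetsigError(Exception):
    """Base class for package errors."""


class FormatError(NetsigError):
    """A file does not parse as the expected on-disk format."""


class UnsupportedInputError(NetsigError):
    """Input is well-formed but outside what the pipeline supports."""


class ParameterError(NetsigError, ValueError):
    """A parameter value violates a precondition."""


class InsufficientDataError(NetsigError):
    """Not enough usable data to satisfy the requested computation."""


class UndefinedMetricError(NetsigError):
    """A metric is mathematically undefined for the given input."""


class EstimatorError(NetsigError):
    """An estimator cannot be evaluated (e.g. too few segments)."""


class FitError(NetsigError):
    """A model fit failed or did not converge."""


class SeparationWarning(UserWarning):
    """Logistic fit detected (quasi-)complete separation."""


class DegenerateInputWarning(UserWarning):
    """Input is degenerate (e.g. all-equal weights); a documented fallback applied."""
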
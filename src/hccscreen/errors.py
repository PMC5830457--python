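"""Exception and warning types shared across the package."""


class CohortFormatError(ValueError):
    """Input table does not conform to the expected cohort layout."""


class EmptyCohortError(ValueError):
    """No usable subject rows after validation."""


class DegenerateGroupError(ValueError):
    """A disease group required by an analysis has no subjects."""


class DegenerateSplitError(ValueError):
    """A sequential model's second-stage training subset is empty or single-class."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a constant (zero-variance) input."""


class CohortSpecError(ValueError):
    """Invalid synthetic-cohort specification."""


class SeparationWarning(UserWarning):
    """Logistic fit detected (quasi-)complete separation; coefficients capped."""
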
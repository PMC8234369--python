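"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A record, cohort, or configuration failed validation.

    The message names the offending field (and the row, for tabular input).
    """


class SeparationError(RuntimeError):
    """Logistic MLE diverged (complete or quasi-complete separation).

    Refit with ``ridge=True`` to obtain a weakly penalized solution, or
    inspect the design for a perfectly predictive covariate.
    """


class DegenerateDataError(ValueError):
    """The data cannot support the requested computation (e.g. a single
    outcome class, or constant predictions where a slope is required)."""
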
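"""Exception hierarchy for the EVOdFNC pipeline.

All errors derive from :class:`EvoDfncError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the pipeline stages.
"""


class EvoDfncError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(EvoDfncError):
    """A parameter violates its documented constraint (e.g. window too short)."""


class InvalidInputError(EvoDfncError):
    """Input data violates a structural precondition (shape, symmetry, range)."""


class DegenerateWindowError(EvoDfncError):
    """A network has zero weighted variance inside a sliding window."""

    def __init__(self, subject_id: str, window: int, network: str):
        self.subject_id = subject_id
        self.window = window
        self.network = network
        super().__init__(
            f"zero-variance network {network!r} in window {window} "
            f"of subject {subject_id!r}"
        )


class SubjectTooShortError(EvoDfncError):
    """A subject has fewer frames than the requested segment length."""


class DegenerateSegmentError(EvoDfncError):
    """A trajectory segment collapses to a single point."""


class DegenerateExemplarError(EvoDfncError):
    """An exemplar has zero length and cannot be sampled."""


class NotFoundError(EvoDfncError, KeyError):
    """A requested subject (or other keyed entity) is unknown."""


class SingularDesignError(EvoDfncError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


class GenerationError(EvoDfncError):
    """The synthetic generator could not produce a valid (SPD) covariance."""


class ValidationError(EvoDfncError):
    """A manifest or configuration failed validation; lists every violation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("validation failed:\n" + "\n".join(f"- {v}" for v in self.violations))
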
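"""Exception hierarchy shared across the package."""


class OcmbTriageError(Exception):
    """Base class for all package-specific errors."""


class InvalidValueError(OcmbTriageError, ValueError):
    """An input value violates a precondition (e.g. a non-positive concentration)."""


class InsufficientDataError(OcmbTriageError, ValueError):
    """Too few observations for the requested computation (e.g. an empty class)."""


class NoFeasibleCutoffError(OcmbTriageError, ValueError):
    """No operating point satisfies the specificity constraint."""


class UndefinedCorrelationError(OcmbTriageError, ValueError):
    """Rank correlation is undefined (a constant vector)."""


class MissingLabelError(OcmbTriageError, ValueError):
    """Samples without an OCMB label were passed where labels are required."""

    def __init__(self, patient_ids):
        self.patient_ids = list(patient_ids)
        super().__init__(
            "samples without an OCMB label: %s" % ", ".join(map(str, self.patient_ids))
        )
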
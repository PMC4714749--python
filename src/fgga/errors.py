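"""Exception hierarchy shared across the package."""


class FggaError(Exception):
    """Base class for all package-specific errors."""


class OntologyStructureError(FggaError):
    """The ontology graph violates a structural invariant (cycle, no root, ...)."""


class UnknownTermError(FggaError, KeyError):
    """A referenced term identifier is absent from the ontology."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class InsufficientDataError(FggaError):
    """Too few samples to carry out an estimation or training step."""


class CalibrationError(FggaError):
    """Sigmoid calibration cannot be fitted (e.g. single-class input)."""


class UndefinedMetricError(FggaError):
    """A metric is undefined for the given input (e.g. AUC with one class)."""
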
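"""Exception hierarchy shared across the toolkit."""


class MbaqError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MbaqError):
    """Input data violates an invariant (bad residue, negative area, ...)."""


class ConfigurationError(MbaqError):
    """A configuration problem: missing column, missing database, bad mapping."""


class CalibrationError(MbaqError):
    """The internal standard cannot be calibrated from the given run."""


class DesignError(MbaqError):
    """No rule-conformant scrambled sequence exists for a peptide."""

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []


class ProteinLookupError(MbaqError, KeyError):
    """The requested protein has no usable observations."""


class SinglePeptideError(MbaqError):
    """Protein identified with a single peptide: excluded from quantification."""
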
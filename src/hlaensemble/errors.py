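"""Exception hierarchy for the hlaensemble package."""


class HlaEnsembleError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlleleError(HlaEnsembleError):
    """Allele name text could not be parsed into gene/field structure."""

    def __init__(self, text: str, reason: str = ""):
        self.text = text
        msg = f"unparseable HLA allele name: {text!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class EmptyReferenceError(HlaEnsembleError):
    """A reference database operation produced zero usable records."""


class UnusableIndexError(HlaEnsembleError):
    """No reference sequence is long enough to yield a single k-mer."""


class PairingError(HlaEnsembleError):
    """Paired FASTQ streams disagree in length or read-name order."""


class UnsupportedToolError(HlaEnsembleError):
    """A tool tag outside the supported vocabulary was requested."""


class SchemaError(HlaEnsembleError):
    """A tabular input is missing a required column."""


class RowError(HlaEnsembleError):
    """A single row of a tabular input violates the record contract."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class LookupError_(HlaEnsembleError):
    """A patient/gene combination is absent from the call matrix."""


class UndefinedMetricError(HlaEnsembleError):
    """A metric's denominator is empty or zero."""


class ConfigurationError(HlaEnsembleError):
    """A simulation or pipeline configuration is internally inconsistent."""
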
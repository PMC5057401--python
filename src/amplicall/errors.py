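"""Exception hierarchy shared across the package."""


class AmplicallError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AmplicallError):
    """A file does not conform to the expected format."""


class ValidationError(AmplicallError):
    """An in-memory object violates its invariants."""


class CoordinateError(AmplicallError):
    """A coordinate falls outside the mapped region."""


class ModelError(AmplicallError):
    """A gene model is internally inconsistent (e.g. broken codon map)."""


class VcfFormatError(FormatError):
    """A VCF line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"VCF line {line_number}: {message}")
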
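"""Exception hierarchy."""


class MidquantError(Exception):
    """Base class for all package errors."""


class ParseError(MidquantError):
    """A raw data file could not be parsed."""


class UnsupportedFormatError(MidquantError):
    """The raw data file format is not one of mzML, mzXML, ANDI netCDF."""


class FormulaError(MidquantError):
    """A molecular formula string could not be parsed."""


class MethodValidationError(MidquantError):
    """A method config violates one or more invariants.

    Carries the full list of violations, not only the first one.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class PeakNotFoundError(MidquantError):
    """No candidate peak passed the detection threshold."""


class EmptyEICError(MidquantError):
    """No scans exist at the requested MS level / precursor."""


class CorrectionError(MidquantError):
    """Natural-abundance correction could not be applied."""


class IllConditionedError(CorrectionError):
    """Correction matrix condition number exceeds the safe limit."""
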
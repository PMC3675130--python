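"""Exception hierarchy for pathgwas."""


class PathgwasError(Exception):
    """Base class for all pathgwas errors."""


class ParseError(PathgwasError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(PathgwasError):
    """Input violated a structural or value constraint."""


class ReconciliationError(ValidationError):
    """Sample/SNP identifiers disagree between paired input files."""


class CalibrationError(PathgwasError):
    """The simulator could not calibrate the baseline risk to the target
    case fraction (planted effects too extreme)."""
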
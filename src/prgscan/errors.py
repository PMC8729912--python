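"""Exception hierarchy.

``PrgScanError`` is the base for everything the library raises on bad
input or impossible requests; the CLI maps it to exit status 2.
"""


class PrgScanError(Exception):
    """Base class for all prgscan errors."""


class SequenceError(PrgScanError):
    """Malformed sequence or FASTA/MSA input."""


class ModelError(PrgScanError):
    """Invalid profile HMM, region table, or model store."""


class CalibrationError(ModelError):
    """A model could not be calibrated against its positive set."""


class ValidationError(PrgScanError):
    """Problems in the prediction-vs-reference comparison."""
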
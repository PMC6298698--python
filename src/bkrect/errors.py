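"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: format/data problems → 3, numerical
failures (non-convergent or degenerate fits, unusable occupancy) → 4,
inference failures → 5.
"""


class BkrectError(Exception):
    """Base class for all package errors."""


class FormatError(BkrectError):
    """Malformed or unsupported input file."""


class FitError(BkrectError):
    """A nonlinear fit failed or is degenerate beyond use."""


class UndefinedRatioError(BkrectError):
    """Rectification ratio undefined (zero inward current)."""


class LowOccupancyError(BkrectError):
    """Occupancy p below the cutoff: the full-occupancy correction would
    amplify noise beyond usefulness."""


class InferenceError(BkrectError):
    """The pairing decision procedure could not produce a result."""
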
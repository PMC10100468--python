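"""Exception hierarchy for the franzq pipeline.

Input/format problems raise :class:`InputError` subclasses (CLI exit code 2);
failures of the analysis itself raise :class:`AnalysisError` subclasses
(CLI exit code 3).
"""


class FranzqError(Exception):
    """Base class for all franzq errors."""


class InputError(FranzqError):
    """Malformed input data or configuration (CLI exit code 2)."""


class InvalidConfigError(InputError):
    """Simulation or run configuration violates its invariants."""


class SpectrumFormatError(InputError):
    """A spectrum file could not be parsed."""


class WindowError(InputError):
    """An integration window does not overlap the spectrum axis or is too narrow."""


class AnalysisError(FranzqError):
    """The computation itself failed (CLI exit code 3)."""


class DegenerateCalibrantError(AnalysisError):
    """Calibrant integral is non-positive: the spectrum is unusable for qNMR."""


class DegenerateInputError(AnalysisError):
    """A quantity that must be non-negative (e.g. an integral ratio) is not."""


class InsufficientDataError(AnalysisError):
    """Too few usable points remain after a transform to fit a model."""


class DegenerateFitError(AnalysisError):
    """The regression design is degenerate (zero variance in x)."""


class NoReleaseError(AnalysisError):
    """A non-positive release slope makes rate/depletion extrapolation meaningless."""
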
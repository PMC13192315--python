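"""Exception hierarchy for the sers_cooccur package.

All package errors derive from :class:`SersCooccurError` so callers can
catch package failures with a single except clause while still being able
to discriminate the failure mode.
"""


class SersCooccurError(Exception):
    """Base class for all package errors."""


class SpectraFormatError(SersCooccurError):
    """Malformed spectral file: ragged rows, non-numeric cells, bad header."""


class AxisError(SersCooccurError):
    """Wavenumber axis violates its invariants (monotonicity, spacing, range)."""


class LabelError(SersCooccurError):
    """Missing, empty or out-of-vocabulary condition labels."""


class CalibrationError(SersCooccurError):
    """Too few calibration pairs or an implausible fitted frequency map."""


class RangeError(SersCooccurError):
    """A wavenumber interval selects no channels."""


class CoverageError(SersCooccurError):
    """An integration window has no axis coverage."""


class ConfigError(SersCooccurError):
    """Invalid generator or pipeline configuration."""


class DegenerateSpectrumError(SersCooccurError):
    """A spectrum that cannot be normalized (all-zero after correction)."""


class SizeError(SersCooccurError):
    """Input too short for the requested operation."""


class CountError(SersCooccurError):
    """A count argument outside its admissible range."""


class StratificationError(SersCooccurError):
    """A class with too few members for a stratified split."""


class SelectionError(SersCooccurError):
    """Empty variable selection where a non-empty one is required."""


class PipelineError(SersCooccurError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
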
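"""Exception hierarchy shared across the package."""


class SersDemuxError(Exception):
    """Base class for all package errors."""


class SpectrumFormatError(SersDemuxError):
    """A spectrum file could not be parsed."""


class EmptyInputError(SersDemuxError):
    """An input file or collection contained no usable data."""


class DegenerateInputError(SersDemuxError):
    """An input is valid in shape but degenerate for the requested operation
    (constant spectrum, zero variance, zero denominator)."""


class GridRangeError(SersDemuxError):
    """A requested wavenumber range falls outside the available data."""


class AlignmentError(SersDemuxError):
    """Two spectra that must share a wavenumber grid do not."""


class ConfigurationError(SersDemuxError):
    """A configuration value violates a structural constraint."""


class ParameterError(SersDemuxError):
    """A numeric parameter is outside its admissible range."""


class TrainingDivergedError(SersDemuxError):
    """The training loss became non-finite."""


class ComparabilityError(SersDemuxError):
    """Evaluation reports refer to different test sets and cannot be compared."""
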
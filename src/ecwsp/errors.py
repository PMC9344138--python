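"""Exception hierarchy for the ecwsp package."""


class ECWSPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ECWSPError, ValueError):
    """A file does not conform to the wide spectral CSV format."""


class DataError(ECWSPError, ValueError):
    """A dataset violates an invariant (non-finite absorbance, inconsistent hierarchy)."""


class ConfigError(ECWSPError, ValueError):
    """An invalid configuration (split plan, generator settings, search parameters)."""


class FitError(ECWSPError, ValueError):
    """Class statistics cannot be estimated from the calibration set."""


class MetricError(ECWSPError, ValueError):
    """Recognition-accuracy metrics cannot be computed (e.g. an empty class)."""


class ModelSpecError(ECWSPError, ValueError):
    """An equidistant wavelength model does not fit on the grid."""


class GridLookupError(ECWSPError, LookupError):
    """A requested wavelength does not lie on the grid."""
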
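"""Exception hierarchy shared by all bandopt modules."""


class BandOptError(Exception):
    """Base class for all bandopt errors."""


class SpectrumParseError(BandOptError):
    """A spectrum text file contains a malformed row."""


class InputError(BandOptError):
    """Input fails a basic precondition (too few points, empty image, ...)."""


class GridError(BandOptError):
    """Two spectra (or a spectrum and a reference) are not on the same grid."""


class RangeError(BandOptError):
    """A wavelength range selects no samples."""


class NormalizationError(BandOptError):
    """A spectrum with zero total intensity cannot be PMF-normalized."""


class BandError(BandOptError):
    """A band lies outside the working wavelength grid."""


class DegenerateBandError(BandOptError):
    """A band captures (near-)zero power, making ratio metrics undefined."""


class EnumerationError(BandOptError):
    """The band-edge lattice is too small to hold two non-overlapping bands."""


class EmptyResultError(BandOptError):
    """No valid band pair survived evaluation."""


class ToleranceError(BandOptError):
    """No evaluated pair matches the requested efficiency tolerance."""


class ZeroVarianceError(BandOptError):
    """A statistic requiring spread is undefined for zero-variance input."""
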
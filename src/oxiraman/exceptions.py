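"""Exception hierarchy shared by all pipeline stages."""


class OxiramanError(Exception):
    """Base class for all package errors."""


class SpectrumValidationError(OxiramanError):
    """A Spectrum violates its invariants (axis, finiteness, coverage)."""


class SpectrumParseError(OxiramanError):
    """A spectrum file could not be parsed; message names the offending line."""


class ManifestError(OxiramanError):
    """A dataset manifest is invalid or references missing files."""


class CoverageError(OxiramanError):
    """An operation's spectral window is not covered by the spectrum axis."""


class NormalizationError(OxiramanError):
    """A normalization divisor is zero, negative or undefined."""


class BaselineError(OxiramanError):
    """Baseline fit is underdetermined or misconfigured."""


class FitError(OxiramanError):
    """A nonlinear fit failed to converge or is degenerate."""


class AmbiguityError(OxiramanError):
    """Band matching found zero or multiple candidates; no silent choice."""


class DesignError(OxiramanError):
    """A calibration design is degenerate or two designs are incompatible."""


class GridError(OxiramanError):
    """Spectra do not share a common wavenumber grid and regridding was not requested."""


class RankError(OxiramanError):
    """Requested latent components exceed the informative rank of the data."""
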
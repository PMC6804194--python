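"""Exception and warning types shared across the package."""


class PasorptionError(Exception):
    """Base class for all package-specific errors."""


class SingularSurfaceError(PasorptionError):
    """The rational parameter surface's denominator vanishes at a condition."""


class InvalidParameterError(PasorptionError):
    """A derived Langmuir parameter is not physically meaningful (<= 0)."""


class DegenerateSystemError(PasorptionError):
    """A batch system cannot be solved (e.g. zero volume with nonzero PA)."""


class FitFailureError(PasorptionError):
    """Nonlinear least squares did not converge or the data are degenerate."""


class UndefinedBaselineError(PasorptionError):
    """Percent desorption is undefined because nothing adsorbed at step 1."""


class ConfigError(PasorptionError):
    """A run configuration is malformed (unknown key, wrong type, missing file)."""


class ExtrapolationWarning(UserWarning):
    """A condition lies outside the calibrated envelope (15-35 degC, 0-15 % v/v)."""


class NegativeConcentrationWarning(UserWarning):
    """An assay conversion produced a negative concentration (floored at zero)."""


class NegativeAdsorptionWarning(UserWarning):
    """Trial concentration exceeded the control mean (net release, q < 0)."""
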
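"""Exception hierarchy shared across the package."""


class ViscowinError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ViscowinError, ValueError):
    """A physical parameter violates its admissible range."""


class ShapeError(ViscowinError, ValueError):
    """Array arguments do not share a common time base / shape."""


class ResolutionError(ViscowinError, ValueError):
    """Time step too coarse for the requested loading frequency."""


class InfeasibleCalibrationError(ViscowinError):
    """Requested target lies outside the reachable range of the model."""


class ConfigError(ViscowinError):
    """Invalid or incomplete run/cohort configuration."""


class DegenerateConfigError(ConfigError):
    """Configuration that makes a stochastic construction undefined (e.g. zero noise)."""


class CalibrationFailureError(ViscowinError):
    """Noise calibration could not reach the requested targets."""


class FormulationParseError(ViscowinError):
    """A formulation table could not be parsed into valid records."""


class RankError(ViscowinError, ValueError):
    """More latent components requested than the predictor matrix supports."""


class SeparationError(ViscowinError):
    """Logistic regression failed to converge (e.g. complete separation)."""
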